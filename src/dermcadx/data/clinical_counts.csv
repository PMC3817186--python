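rater,category,class,group,n_correct,n_incorrect
dermatologist,blue_nevus,benign,melanocytic,19,3
dermatologist,compound_nevus,benign,melanocytic,50,3
dermatologist,congenital_nevus,benign,melanocytic,9,0
dermatologist,dermatofibroma,benign,non_melanocytic,47,2
dermatologist,dysplastic_nevus,benign,melanocytic,1,1
dermatologist,epidermal_nevus,benign,non_melanocytic,3,0
dermatologist,hemangioma,benign,non_melanocytic,35,3
dermatologist,intradermal_nevus,benign,melanocytic,209,31
dermatologist,junctional_nevus,benign,melanocytic,39,7
dermatologist,lentigo_simplex,benign,melanocytic,0,1
dermatologist,nevus_lipomatosus_superficialis,benign,non_melanocytic,1,0
dermatologist,nevus_sebaceous,benign,non_melanocytic,2,0
dermatologist,nevus_spilus,benign,melanocytic,2,0
dermatologist,seborrheic_keratosis,benign,non_melanocytic,94,33
dermatologist,bcc,malignant,non_melanocytic,97,13
dermatologist,cutaneous_melanoma,malignant,melanocytic,6,2
dermatologist,kaposi_sarcoma,malignant,non_melanocytic,11,3
dermatologist,keratoacanthoma,malignant,non_melanocytic,14,8
dermatologist,scc,malignant,non_melanocytic,17,3
cadx,blue_nevus,benign,melanocytic,20,2
cadx,compound_nevus,benign,melanocytic,47,6
cadx,congenital_nevus,benign,melanocytic,6,3
cadx,dermatofibroma,benign,non_melanocytic,48,1
cadx,dysplastic_nevus,benign,melanocytic,1,1
cadx,epidermal_nevus,benign,non_melanocytic,2,1
cadx,hemangioma,benign,non_melanocytic,23,15
cadx,intradermal_nevus,benign,melanocytic,225,15
cadx,junctional_nevus,benign,melanocytic,42,4
cadx,lentigo_simplex,benign,melanocytic,1,0
cadx,nevus_lipomatosus_superficialis,benign,non_melanocytic,0,1
cadx,nevus_sebaceous,benign,non_melanocytic,2,0
cadx,nevus_spilus,benign,melanocytic,2,0
cadx,seborrheic_keratosis,benign,non_melanocytic,102,25
cadx,bcc,malignant,non_melanocytic,99,11
cadx,cutaneous_melanoma,malignant,melanocytic,6,2
cadx,kaposi_sarcoma,malignant,non_melanocytic,10,4
cadx,keratoacanthoma,malignant,non_melanocytic,18,4
cadx,scc,malignant,non_melanocytic,16,4
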