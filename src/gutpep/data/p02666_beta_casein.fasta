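>P02666 Beta-casein (Bos taurus), mature chain (signal peptide removed), 209 aa
RELEELNVPGEIVESLSSSEESITRINKKIEKFQSEEQQQTEDELQDKIHPFAQTQSLVY
PFPGPIPNSLPQNIPPLTQTPVVVPPFLQPEVMGVSKVKEAMAPKHKEMPFPKYPVEPFT
ESQSLTLTDVENLHLPLPLLQSWMHQPHQPLPPTVMFPPQSVLSLSQSKVLPVPQKAVPY
PQRDMPIQAFLLYQEPVLGPVRGPFPIIV
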