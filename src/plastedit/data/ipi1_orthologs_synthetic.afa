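>Nicotiana_benthamiana
ICCEMPQMWFGPGMFRGFVHNKDEWESWHKPTLWMGAECDNGTCNIADSFQMVDPDNVANRIKMFDIRGIQVVEWYQPKMNVRWEYFMESDNW
>Nicotiana_tabacum
ICCEMPQMWFGPGMFRGFVHNKDEWESWHKPTLWMGAECRNGTCNIADSFQMVDPDNVANYIKMFDGRGAQVTEWYQPKMNVLWEYFMESDNW
>Solanum_lycopersicum
ICCEMPWMWFGPGMFRGFVHNKEEWESWHHPTLWMGAECDSFTCNIADSFQMVDPDNVANYIKMFDGRGRQVTEWYQPKMNVRWEYFMESDNW
>Arabidopsis_thaliana
ICCEMPQMWFGPGMFRCFVHNKCENESWFKPTLWMGAECDNGTCNIADSFQMVNPDNVANYIKMFDGRGRQVTEWYQPKMNVRWEYFMESDLW
>Glycine_max
ICCEMPQMWFGPGMFRGFVHNKDEWESWHKPTLDMGAECDNGTCNIADSFQMVDPDNVANYIPMFDGRGRQVTAWYQPKMNVRWEYFMESDLW
>Zea_mays
ICCEPPIMEAGPWMARGANSMKQTMESTYKPTLWMGMGCDNDCCNASDSFQMCDPDMVANYIKMFDGRRRQVTEWYQPKMDPGWEYLNEQ---
>Sorghum_bicolor
ICCEPPIMEAGPGMARGANSMKQTMESWYKPTLWMGMCGDNDCCNASIEFQMCDPDYVANYIKMFDGRRRQVTEWYQPKMDVGWEYLNEQ---
>Oryza_sativa
ICCEPFIMEASPGMARGDNSMKQTMESWYKPTLWMGMCCDNDCANAKDSFQMCDPDYVANYIKMFDGRRRQVTEWYQPKMDVGWEYLNEQ---
>Brachypodium_distachyon
ICCEPPIMEAGPGMAREANSMKQTMESWYKPTLWMGMCCDNDCCNASDSFQMCDPDYVANYIKMFDGRRWQVTEWYNPKMDVGWEYLNEQ---
>Physcomitrium_patens
ICEEMPQMWAGPGMHRGFNHNPQTWESWHKPTLWMGAECANGCTNIARSFQMVDPDNVVNYITMFDGRRRQITEWYQPKINVGWEYFNESDYW
>Marchantia_polymorpha
ICCEMPQMWAPPGMARGFNSNKQTWESNHKCTLWMGAQCDNGCANIANSFQMYDPDNVANYIKMFDGRRRQVTEWYQPKMNVGWEYHNESDYW
>Ceratopteris_richardii
ISCEMPQMWAGPGMARGFNHYKQMWESNHKPTLSMGAECDNGCCNIADSFDMVDPDVVANYIKMGDGRRRQVTEWYQPVMNAGWEYHNEWDYW
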