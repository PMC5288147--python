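>K1_2B_ref
ELAELKNELAELKNELAELKNELAELKNELRELKNELAELKNELAELKNELAELKDELQRLKNELADLKNELAELKNALAELKNDLAELKRDLAELKNTKAELDNEIATYRRLLEGEENEL
>K1_homolog_1
ELAELKNELAELKNELAELKNELAELKNELRELKNELAELKNELAELKNELAELKDELQRLKNELADLKNELAELKNALAELKNDLAELKRDLAELKNTKAELDNEIATYRRLLEGEENEL
>K1_homolog_2
SFCSFSSSFCSFSSSFCSFSSSFCSFSSSFRSFSSSFCSFSSSFCSFSSSFCSFSDSFQRFSNSLCDFSSSFCSFSSAFCSFSSDFCSFSRDFCSFSSVSCSFGSEICTYEELLSASSSSF
>K1_homolog_3
SFCSFSSSFCSFSSSFCSFSSSFCSFSSSFHSFSSSFCSFSSSFCSFSSSFCSFSWSFWWFSWSWCWFSSSFCSFSSWFCSFSSEFCSFSWEFCSFSSVSCSFGSEICTYEELLSASSSSF
>K1_homolog_4
SVCSVSSSVCSVSSSVCSVSSSVCSVSSSVHSVSSSVCSVSSSVCSVSSSVCSVSWSVWWVSWSWCWVSSSVCSVSSWVCSVSSEVCSVSWEVCSVSSVSCSVGSEICTYEELLSASSSSV
>K1_homolog_5
ELAELKNELAELKNELAELKNELAELKNELRELKNELAELKNELAELKNELAELKDELQRLKNELADLKNELAELKNALAELKNDLAELKRDLAELKNTKAELDNEIATYRRLLEGEENEL
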