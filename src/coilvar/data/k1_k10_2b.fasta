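>K1_2B positions 373-493
ELAELKNELAELKNELAELKNELAELKNELRELKNELAELKNELAELKNELAELKDELQRLKNELADLKNELAELKNALAELKNDLAELKRDLAELKNTKAELDNEIATYRRLLEGEENEL
>K10_2B positions 340-460
ELKNELAELKNELAELKNELAELKNELAELKNELAELKNEQAELKNELAELKNELAELKRELAQLKNELAQLKNELAELKQELAELKNELAELKNELAEKKNLEAEIQTYRSLLEGELAEL
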