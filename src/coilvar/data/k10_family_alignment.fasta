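>K10_2B_ref
ELKNELAELKNELAELKNELAELKNELAELKNELAELKNEQAELKNELAELKNELAELKRELAQLKNELAQLKNELAELKQELAELKNELAELKNELAEKKNLEAEIQTYRSLLEGELAEL
>K10_homolog_1
ELKNELAELKNELAELKNELAELKNELAELKNELAELKNEQAELKNELAELKNELAELKRELAQLKNELAQLKNELAELKQELAELKNELAELKNELAEKKNLEAEIQTYRSLLEGELAEL
>K10_homolog_2
SFSSSFCSFSSSFCSFSSSFCSFSSSFCSFSSSFCSFSSSQCSFSSSFCSFSSSFCSFSRSFCSFSSSFCQFSSSFCSFSQSFCSFSSSFCSFSSSFCSKSSLECEIQVYESLLSASFCSF
>K10_homolog_3
SFSSSFCSFSSSFCSFSSSFCSFSSSFCSFSSSFCSFSSSWCSFSSSFCSFSSSFCSFSHSFCSFSSSFCWFSSSFCSFSWSFCSFSSSFCSFSSSFCSKSSLECEIQVYEWLLSASFCSF
>K10_homolog_4
SVSSSVCSVSSSVCSVSSSVCSVSSSVCSVSSSVCSVSSSWCSVSSSVCSVSSSVCSVSHSVCSVSSSVCWVSSSVCSVSWSVCSVSSSVCSVSSSVCSKSSLECEIQVYEWLLSASVCSV
>K10_homolog_5
ELKNELAELKNELAELKNELAELKNELAELKNELAELKNEQAELKNELAELKNELAELKRELAQLKNELAQLKNELAELKQELAELKNELAELKNELAEKKNLEAEIQTYRSLLEGELAEL
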