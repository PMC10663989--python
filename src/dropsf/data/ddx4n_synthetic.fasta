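>ddx4n_1-231_synthetic designed Ddx4N-like stand-in (GAMGS leader, alternating charge blocks, no Cys); net charge -2.14 e at pH 8
GAMGSGSNYFGSQMGYAPSRKRKGSNGYGSQMGTYPSDEDEGSNGFYSQMGTAYSRKRK
GSNGFGYQMGTAPYDEDEGSNGFGSYMGTAPSRKRKYSNGFGSQYGTAPSDEDEGYNGF
GSQMYTAPSRKRKGSNYFGSQMGYAPSDEDEGSNGYGSQMGTYPSRKRKGSNGFYSQMG
TAYSDEDEGSNGFGYQMGTAPYRKRRGSNGFGSYMGTAPSDEDEHSNGFGSQHGTAPEA
>ddx4n_1-229_synthetic designed Ddx4N-like stand-in, C-terminal EA truncation of ddx4n_1-231_synthetic; net charge -1.14 e at pH 8
GAMGSGSNYFGSQMGYAPSRKRKGSNGYGSQMGTYPSDEDEGSNGFYSQMGTAYSRKRK
GSNGFGYQMGTAPYDEDEGSNGFGSYMGTAPSRKRKYSNGFGSQYGTAPSDEDEGYNGF
GSQMYTAPSRKRKGSNYFGSQMGYAPSDEDEGSNGYGSQMGTYPSRKRKGSNGFYSQMG
TAYSDEDEGSNGFGYQMGTAPYRKRRGSNGFGSYMGTAPSDEDEHSNGFGSQHGTAP
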