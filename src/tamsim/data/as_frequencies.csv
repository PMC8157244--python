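group,as_class,frequency
American,0,0.0218
American,0.5,0.0146
American,1,0.221
American,1.5,0.0724
American,2,0.614
American,>2,0.0561
African American/Afro-Caribbean,0,0.0233
African American/Afro-Caribbean,0.5,0.105
African American/Afro-Caribbean,1,0.258
African American/Afro-Caribbean,1.5,0.321
African American/Afro-Caribbean,2,0.247
African American/Afro-Caribbean,>2,0.0467
Central/South Asian,0,0.0234
Central/South Asian,0.5,0.0736
Central/South Asian,1,0.222
Central/South Asian,1.5,0.258
Central/South Asian,2,0.399
Central/South Asian,>2,0.0248
East Asian,0,0.00865
East Asian,0.5,0.279
East Asian,1,0.112
East Asian,1.5,0.366
East Asian,2,0.220
East Asian,>2,0.0138
European,0,0.0647
European,0.5,0.0752
European,1,0.314
European,1.5,0.170
European,2,0.345
European,>2,0.0313
Latino,0,0.0312
Latino,0.5,0.0477
Latino,1,0.243
Latino,1.5,0.170
Latino,2,0.462
Latino,>2,0.0458
Near Eastern,0,0.0220
Near Eastern,0.5,0.0834
Near Eastern,1,0.215
Near Eastern,1.5,0.267
Near Eastern,2,0.309
Near Eastern,>2,0.104
Oceanian,0,0.00383
Oceanian,0.5,0.00482
Oceanian,1,0.0961
Oceanian,1.5,0.0522
Oceanian,2,0.637
Oceanian,>2,0.206
Sub-Saharan African,0,0.0153
Sub-Saharan African,0.5,0.123
Sub-Saharan African,1,0.312
Sub-Saharan African,1.5,0.317
Sub-Saharan African,2,0.186
Sub-Saharan African,>2,0.0470
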