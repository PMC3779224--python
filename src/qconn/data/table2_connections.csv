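subject,DSIq5b8000(1),DSIq5b8000(2),DSIq5b8000(3),DSIq5b6400,DSIq4,QBI,DTI65,DTI21
1,12755,12709,12386,12411,10736,10915,10052,9882
2,14119,13848,13720,13812,12227,11759,10778,11134
3,13570,14256,13535,13441,11142,11084,10456,10829
4,13543,13597,13504,12952,11238,11258,9760,10206
5,13757,13282,13800,13795,11737,11372,10506,10455
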