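(((olivieri_azerbayjan:0.15,caucasica:0.15):0.2,(olivieri_shabestar:0.2,persica_khorasan:0.2):0.15):0.25,((anisodonta:0.18,(bruguieri:0.12,rigida:0.12):0.06):0.2,(kurdica:0.2,(persica:0.1,olivieri_kordestan:0.1):0.1):0.18):0.22,((olivieri_tabriz:0.25,persica_dehgolan:0.25):0.15,(olivieri_mazandaran:0.22,(anisodonta_mazandaran:0.15,anisodonta_polezangole:0.15):0.07):0.18):0.2);
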