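sample,replicate,area,rf
olivieri_azerbayjan,1,257559.8,0.65
olivieri_tabriz,1,461645.8,0.65
olivieri_mazandaran,1,479058.9,0.65
bruguieri,1,506145.9,0.65
kurdica,1,393148.1,0.65
rigida,1,515808.8,0.65
anisodonta,1,578081.9,0.65
persica,1,463498.0,0.65
caucasica,1,264396.1,0.65
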