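level,concentration,area
1,3.0,212619.3
2,6.0,363006.8
3,9.0,462891.9
4,12.0,614373.5
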