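>zma-miR156a-5p
UGACAGAAGAGAGUGAGCAC
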