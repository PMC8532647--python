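name	neutral_mass
alprostadil	354.240624
caffeine	194.080376
midazolam	325.078203
fentanyl	336.220164
paracetamol	151.063329
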