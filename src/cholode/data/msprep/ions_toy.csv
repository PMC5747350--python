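mass,intensity
480.0317,10000.0
480.0315,1000.0
147.066283,5000.0
167.0719,3000.0
145.014247,8000.0
300.0,9000.0
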