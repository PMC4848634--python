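name	ring	exocyclic	source
AP A	K,V,Hty,MeAla,F	Tyr	literature
AP B	K,V,Hty,MeAla,F	R	literature
AP F	K,Ile,Hty,MeAla,F	R	literature
OSC Y	K,Ile,Hty,MeAla,F	Tyr	literature
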