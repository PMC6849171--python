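modifier	grade
reasonably	2
fairly	2
somewhat	2
quite	2
moderately	2
mostly	2
fully	3
very	3
completely	3
totally	3
extremely	3
highly	3
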