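modifier	grade
slightly	2
somewhat	2
occasionally	2
partly	2
moderately	2
a-little	2
severely	3
completely	3
totally	3
greatly	3
significantly	3
massively	3
badly	3
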