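modifier	grade
mild	2
slight	2
occasional	2
intermittent	2
moderate	2
morning	2
minor	2
severe	3
constant	3
terrible	3
extreme	3
persistent	3
chronic	3
considerable	3
awful	3
bad	3
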