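modifier	grade
pain-free	1
painless	1
mild	2
slight	2
occasional	2
intermittent	2
dull	2
minor	2
moderate	2
nagging	2
general	2
momentary	2
niggling	2
severe	3
sharp	3
constant	3
bad	3
stabbing	3
shooting	3
burning	3
excruciating	3
unbearable	3
overwhelming	3
agonising	3
chronic	3
persistent	3
throbbing	3
acute	3
terrible	3
awful	3
horrible	3
extreme	3
intense	3
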