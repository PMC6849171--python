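modifier	grade
worse	1
worsened	1
deteriorated	1
same	2
unchanged	2
similar	2
stable	2
better	3
improved	3
improving	3
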