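term	score
pain	-0.7
ache	-0.6
stiffness	-0.5
swelling	-0.5
bruising	-0.4
discomfort	-0.5
soreness	-0.5
unbearable	-1.0
excruciating	-1.0
overwhelming	-0.8
agonising	-0.9
severe	-0.8
terrible	-0.9
awful	-0.9
horrible	-0.9
dreadful	-0.9
scream	-0.8
cry	-0.8
regret	-0.7
worse	-0.8
worst	-1.0
bad	-0.7
badly	-0.7
struggle	-0.6
unable	-0.7
difficult	-0.5
hard	-0.4
worried	-0.6
unsure	-0.4
afraid	-0.6
nervous	-0.5
anxious	-0.6
frustrated	-0.7
frustrating	-0.7
disappointed	-0.7
disappointing	-0.7
agony	-1.0
hurt	-0.6
sore	-0.5
weak	-0.4
unstable	-0.5
wobbly	-0.4
swollen	-0.5
stiff	-0.5
uncomfortable	-0.5
painful	-0.8
annoying	-0.5
miserable	-0.8
sadly	-0.5
unhappy	-0.7
useless	-0.7
hopeless	-0.8
great	0.8
good	0.6
better	0.7
best	0.9
improve	0.7
improved	0.7
improvement	0.7
improving	0.7
happy	0.8
pleased	0.8
confident	0.6
fine	0.5
excellent	0.9
fantastic	0.9
wonderful	0.9
brilliant	0.9
comfortable	0.5
strong	0.4
progress	0.5
recover	0.6
recovering	0.6
relief	0.6
relieved	0.6
grateful	0.8
hopeful	0.6
amazing	0.9
helpful	0.6
helped	0.5
easy	0.4
easier	0.5
normal	0.3
pain-free	0.8
painless	0.8
delighted	0.9
thankful	0.8
satisfied	0.7
positive	0.6
manageable	0.4
encouraged	0.6
encouraging	0.6
stronger	0.5
steady	0.3
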