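concept_id	name	semantic_type
K0001	osteoarthritis	cond
K0001	OA	cond
K0001	degenerative joint disease	cond
K0002	arthritis	cond
K0003	rheumatoid arthritis	cond
K0004	meniscus tear	cond
K0004	torn meniscus	cond
K0004	torn cartilage	cond
K0005	ACL rupture	cond
K0005	ruptured ACL	cond
K0005	completely ruptured	cond
K0006	ACL tear	cond
K0006	torn ACL	cond
K0007	sprain	cond
K0007	sprained knee	cond
K0008	tendonitis	cond
K0008	tendinitis	cond
K0009	patellofemoral pain syndrome	cond
K0009	runner's knee	cond
K0010	bursitis	cond
K0011	dislocation	cond
K0011	dislocated kneecap	cond
K0012	fracture	cond
K0012	broken kneecap	cond
K0013	ligament damage	cond
K0013	ligament injury	cond
K0014	cartilage damage	cond
K0015	chondromalacia	cond
K0016	baker's cyst	cond
K0017	hyperextension	cond
K0018	MCL sprain	cond
K0019	jumper's knee	cond
K0019	patellar tendinopathy	cond
K0101	knee	anat
K0101	knee joint	anat
K0102	ACL	anat
K0102	anterior cruciate ligament	anat
K0103	PCL	anat
K0103	posterior cruciate ligament	anat
K0104	MCL	anat
K0104	medial collateral ligament	anat
K0105	meniscus	anat
K0106	kneecap	anat
K0106	patella	anat
K0107	cartilage	anat
K0108	hamstring	anat
K0109	quadriceps	anat
K0109	quads	anat
K0110	ligament	anat
K0111	tendon	anat
K0112	calf	anat
K0113	shin	anat
K0201	reconstruction surgery	proc
K0201	reconstructive surgery	proc
K0202	hamstring graft	proc
K0203	knee replacement	proc
K0203	knee arthroplasty	proc
K0203	total knee replacement	proc
K0204	arthroscopy	proc
K0204	keyhole surgery	proc
K0205	meniscectomy	proc
K0206	physiotherapy	proc
K0206	physio	proc
K0206	physical therapy	proc
K0207	steroid injection	proc
K0207	cortisone injection	proc
K0208	surgery	proc
K0208	operation	proc
K0209	hydrotherapy	proc
K0210	acupuncture	proc
K0211	massage	proc
K0212	meniscus repair	proc
K0301	ibuprofen	drug
K0301	nurofen	drug
K0302	paracetamol	drug
K0302	acetaminophen	drug
K0303	naproxen	drug
K0304	codeine	drug
K0305	anti-inflammatories	drug
K0305	anti-inflammatory tablets	drug
K0305	NSAIDs	drug
K0306	painkillers	drug
K0306	pain killers	drug
K0306	analgesics	drug
K0307	glucosamine	drug
K0401	knee brace	devi
K0401	brace	devi
K0402	crutches	devi
K0403	knee support	devi
K0403	compression sleeve	devi
K0404	walking stick	devi
K0404	cane	devi
K0405	ice pack	devi
K0406	tubigrip	devi
K0407	orthotics	devi
K0501	squats	exac
K0502	lunges	exac
K0503	stretching exercises	exac
K0503	stretches	exac
K0504	leg raises	exac
K0504	straight leg raises	exac
K0505	strengthening exercises	exac
K0506	balance exercises	exac
K0507	step ups	exac
K0508	cardiovascular exercises	exac
K0508	cardio	exac
K0509	wall sits	exac
K0510	heel slides	exac
K0511	bridging	exac
K0601	pain	sosy
K0602	ache	sosy
K0602	aching	sosy
K0603	stiffness	sosy
K0604	swelling	sosy
K0604	edema	sosy
K0604	oedema	sosy
K0604	dropsy	sosy
K0605	bruising	sosy
K0606	numbness	sosy
K0607	tingling	sosy
K0607	pins and needles	sosy
K0608	weakness	sosy
K0609	instability	sosy
K0609	giving way	sosy
K0610	clicking	sosy
K0611	popping	sosy
K0612	grinding	sosy
K0612	crepitus	sosy
K0613	locking	sosy
K0614	catching	sosy
K0615	discomfort	sosy
K0616	soreness	sosy
K0617	throbbing	sosy
K0618	tightness	sosy
K0619	warmth	sosy
K0620	redness	sosy
K0621	tenderness	sosy
K0622	buckling	sosy
K0701	exercise	dora
K0702	hobby	dora
K0702	hobbies	dora
K0703	squash	dora
K0704	golf	dora
K0705	walking	dora
K0706	running	dora
K0706	jogging	dora
K0707	cycling	dora
K0708	swimming	dora
K0709	gardening	dora
K0710	shopping	dora
K0711	driving	dora
K0712	football	dora
K0713	tennis	dora
K0714	yoga	dora
K0715	dancing	dora
K0716	hiking	dora
K0717	housework	dora
K0718	cooking	dora
K0719	dog walking	dora
K0720	climbing stairs	dora
K0721	gym	dora
K0722	rugby	dora
K0723	netball	dora
K0724	badminton	dora
K0725	skiing	dora
K0726	fishing	dora
K0727	bowling	dora
K0728	daily tasks	dora
K0729	sport	dora
K0801	job	ocdi
K0802	occupation	ocdi
K0803	profession	ocdi
K0804	career	ocdi
K0851	work	ocac
K0852	shift	ocac
K0853	manual labour	ocac
K0854	duties	ocac
K0901	vehicle mechanic	prog
K0902	nurse	prog
K0903	teacher	prog
K0904	builder	prog
K0905	electrician	prog
K0906	plumber	prog
K0907	carer	prog
K0908	delivery driver	prog
K0909	shop assistant	prog
K0910	farmer	prog
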