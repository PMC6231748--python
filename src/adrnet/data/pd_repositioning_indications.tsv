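labeled_indication	drug
immunomodulatory	thalidomide
multiple sclerosis	glatiramer acetate
asthma	salbutamol
depression	bupropion
depression	citalopram
depression	clomipramine
depression	paroxetine
depression	sertraline
depression	fluoxetine
depression	fluvoxamine
depression	mirtazapine
depression	nefazodone
alzheimer disease	donepezil
alzheimer disease	rivastigmine
epilepsy	carbamazepine
epilepsy	gabapentin
epilepsy	lamotrigine
epilepsy	levetiracetam
epilepsy	topiramate
epilepsy	valproic acid
epilepsy	oxcarbazepine
epilepsy	phenytoin
fatigue	methylphenidate
fatigue	modafinil
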