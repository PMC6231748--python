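drug	positive	negative
amphotericin b	1	1
bupropion	1	0
carbamazepine	1	0
citalopram	1	1
clomipramine	1	0
diltiazem	0	1
donepezil	1	0
fluoxetine	1	0
fluvoxamine	1	0
gabapentin	1	1
glatiramer acetate	1	0
lamotrigine	1	1
levetiracetam	1	0
methylphenidate	1	0
mirtazapine	1	0
modafinil	1	0
nefazodone	1	0
oxcarbazepine	1	0
paroxetine	1	0
phenytoin	1	0
rivastigmine	1	0
salbutamol	1	0
sertraline	1	0
thalidomide	1	0
topiramate	1	0
tramadol	0	1
valproic acid	1	0
ziprasidone	1	1
alprazolam	0	0
budesonide	0	0
clarithromycin	0	0
granisetron	0	0
lansoprazole	0	0
levonorgestrel	0	0
mefloquine	0	0
mycophenolic acid	0	0
omeprazole	0	0
tacrolimus	0	0
tiagabine	0	0
tobramycin	0	0
topotecan	0	0
valganciclovir	0	0
venlafaxine	0	0
vigabatrin	0	0
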