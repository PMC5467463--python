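lemma	inflections	category	polarity	nominal_forms
reduce	reduces,reduced,reducing	NegativeRegulation	-1	reduction,reductions
decrease	decreases,decreased,decreasing	NegativeRegulation	-1
suppress	suppresses,suppressed,suppressing	NegativeRegulation	-1	suppression
block	blocks,blocked,blocking	NegativeRegulation	-1
down-regulate	down-regulates,down-regulated,down-regulating,downregulate,downregulates,downregulated	NegativeRegulation	-1	down-regulation,downregulation
inhibit	inhibits,inhibited,inhibiting	NegativeRegulation	-1	inhibition,inhibitor,inhibitors
prevent	prevents,prevented,preventing	NegativeRegulation	-1	prevention
attenuate	attenuates,attenuated,attenuating	NegativeRegulation	-1	attenuation
repress	represses,repressed,repressing	NegativeRegulation	-1	repression
increase	increases,increased,increasing	PositiveRegulation	1
induce	induces,induced,inducing	PositiveRegulation	1	induction
activate	activates,activated,activating	PositiveRegulation	1
enhance	enhances,enhanced,enhancing	PositiveRegulation	1	enhancement
up-regulate	up-regulates,up-regulated,up-regulating,upregulate,upregulates,upregulated	PositiveRegulation	1	up-regulation,upregulation
stimulate	stimulates,stimulated,stimulating	PositiveRegulation	1	stimulation
promote	promotes,promoted,promoting	PositiveRegulation	1	promotion
cleave	cleaves,cleaved,cleaving	Cleavage	-1	cleavage
interact	interacts,interacted,interacting	BindingEvent	0	interaction,interactions
bind	binds,bound,binding	BindingEvent	0
associate	associates,associated,associating	BindingEvent	0	association,associations
complex	complexed	BindingEvent	0	complex,complexes
translocate	translocates,translocated,translocating	TransportEvent	0	translocation,translocations
phosphorylate	phosphorylates,phosphorylated,phosphorylating	Phosphorylation	0	phosphorylation
express	expresses,expressed,expressing	Expression	0	expression
activity		Activity	0	activity,activities
mediate	mediates,mediated,mediating	Generic	0
protect	protects,protected,protecting	Generic	0	protection
signal	signals,signaled,signalled	Generic	0	signaling,signalling
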