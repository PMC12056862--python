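name	prevalence	rrr	modifiable	effectiveness
Low education	20%	7%	No	N/A
Hearing loss	30%	8%	Yes	50%
Hypertension	40%	2%	Yes	70%
Smoking	25%	5%	Yes	60%
Obesity	30%	1%	Yes	40%
Depression	20%	4%	Yes	50%
Physical inactivity	50%	3%	Yes	50%
Diabetes	25%	1%	Yes	50%
Excessive alcohol use	15%	1%	Yes	50%
Traumatic brain injury	10%	3%	No	N/A
Air pollution	30%	2%	Yes	30%
Social isolation	40%	4%	Yes	60%
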