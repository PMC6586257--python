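icd_version	icd_code	phecode	exclusion_root	description	category
10	D60	284	284	Aplastic anemia	Hematopoietic
10	D61	284	284	Aplastic anemia	Hematopoietic
10	D649	285	280	Other anemias	Hematopoietic
10	D509	280.1	280	Iron deficiency anemias, unspecified or not due to blood loss	Hematopoietic
9	2809	280.1	280	Iron deficiency anemias, unspecified or not due to blood loss	Hematopoietic
10	D510	281	280	Other deficiency anemia	Hematopoietic
10	D529	281	280	Other deficiency anemia	Hematopoietic
10	D62	285.1	280	Acute posthemorrhagic anemia	Hematopoietic
10	E780	272.11	272	Hypercholesterolemia	Endocrine/metabolic
9	2720	272.11	272	Hypercholesterolemia	Endocrine/metabolic
10	L08	686	680	Other local infections of skin and subcutaneous tissue	Dermatologic
10	L089	686	680	Other local infections of skin and subcutaneous tissue	Dermatologic
10	L98	689	680	Disorder of skin and subcutaneous tissue NOS	Dermatologic
10	K140	529.1	529	Glossitis	Digestive
10	T360	960	960	Poisoning by antibiotics	Injuries and poisonings
10	L0311	681.3	680	Cellulitis and abscess of arm/hand	Dermatologic
10	L0303	681.6	680	Cellulitis and abscess of foot, toe	Dermatologic
10	L0312	681.5	680	Cellulitis and abscess of leg, except foot	Dermatologic
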