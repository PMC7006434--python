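id	formula	description	gpr	subsystem
T1	Tibolone[e] <=>	Tibolone exchange reaction		Steroid metabolism
T2	Tibolone[e] <=> a3OHtibolone[e]	3a-hydroxytibolone interconversion	CYP27A1	Steroid metabolism
T3	Tibolone[e] <=> b3OHtibolone[e]	3b-hydroxytibolone interconversion	CYP27A1	Steroid metabolism
T4	Tibolone[e] -> d4tibolone[e]	D4-tibolone isomer formation		Steroid metabolism
T5	b3OHtibolone[e] -> d4tibolone[e]	D4-tibolone isomer formation from 3b-hydroxytibolone		Steroid metabolism
T6	a3OHtibolone[e] -> estradiol[c]	Estradiol receptor agonist action of 3a-hydroxytibolone	ADH4 or ADH5 or ADH7	Steroid metabolism
T7	b3OHtibolone[e] -> estradiol[c]	Estradiol receptor agonist action of 3b-hydroxytibolone	ADH4 or ADH5 or ADH7	Steroid metabolism
T8	d4tibolone[e] -> prgstrn[c] + tststerone[c]	Progesterone and androgen receptor activation by the D4 isomer		Steroid metabolism
T9	a3OHtibolone[e] <=> a3SOtibolone[e]	3a-hydroxytibolone interconversion to sulfated inactive compound		Steroid metabolism
T10	a3SOtibolone[e] ->	Inactive sulfated form leaves the system		Steroid metabolism
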