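protein_id	outcome_id	mr_or	smr_or	p_smr	p_heidi	pph4_pqtl	pph4_eqtl	eqtl_available
CRYZ	knee_oa	0.874	NA	NA	NA	NA	NA	True
MAPK3	knee_oa	0.855	0.929	8.87e-4	0.5	0.843	0.930	True
LGALS3	knee_oa	1.120	1.638	3.87e-3	0.5	0.828	NA	True
GZMK	knee_oa	1.278	1.240	7.97e-5	0.5	0.949	0.960	True
MAX	knee_oa	0.823	0.844	4.55e-4	0.5	NA	NA	True
CFHR3	knee_oa	0.726	NA	NA	NA	NA	NA	False
OMG	knee_oa	0.647	2.080	1.49e-5	0.5	NA	0.831	True
DNAJB12	knee_oa	1.552	1.298	3.16e-5	0.01	0.832	NA	True
ITIH1	hip_oa	0.847	NA	NA	NA	0.844	NA	False
CRYZ	knee_or_hip_oa	0.882	0.977	1.33e-2	0.5	NA	NA	True
ULK3	knee_or_hip_oa	0.695	0.943	2.85e-4	0.01	NA	NA	True
USP8	knee_or_hip_oa	1.450	0.894	1.03e-5	0.01	0.804	0.805	True
CSK	knee_or_hip_oa	0.622	0.914	1.15e-4	0.5	NA	NA	True
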