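coid	canonical_name	alt_names	type_id	type_name
COID000001	manganese	Mn|manganese chloride|MnCl2	C013	trace metals or minerals
COID000002	copper chloride	CuCl2|copper	C013	trace metals or minerals
COID000003	nickel	Ni	C013	trace metals or minerals
COID000004	iron	Fe	C013	trace metals or minerals
COID000005	glycosylation	N-linked glycosylation|N-glycosylation	C004	glycosylation
COID000006	afucosylation		C004	glycosylation
COID000007	galactosylation		C004	glycosylation
COID000008	sialylation		C004	glycosylation
COID000009	core fucosylation		C004	glycosylation
COID000010	ADCC	antibody-dependent cellular cytotoxicity|antibody-dependent cell-mediated cytotoxicity|antibody-dependent cell cytotoxicity	C018	clinical outcomes
COID000011	pH	culture pH	C015	bioreactor conditions
COID000012	osmolality		C015	bioreactor conditions
COID000013	pCO2	partial pressure of CO2|partial carbon dioxide pressure	C015	bioreactor conditions
COID000014	potency		C017	product quality attributes
COID000015	safety		C018	clinical outcomes
COID000016	immunogenicity		C018	clinical outcomes
COID000017	pharmacokinetic clearance	clearance	C018	clinical outcomes
COID000018	apoptosis		C002	biological processes
COID000019	cell cycle		C002	biological processes
COID000020	vesicular trafficking	intracellular vesicular trafficking	C002	biological processes
COID000021	cell death		C002	biological processes
COID000022	productivity	specific productivity|qp	C019	process performance
COID000023	product quality		C017	product quality attributes
COID000024	viable cell density	VCD	C019	process performance
COID000025	culture medium	medium|media|media selection|on-demand medium	C008	secondary raw materials
COID000026	by-product formation	by-product	C007	by-product or waste
COID000027	sucrose		C010	disaccharide
COID000028	maltose		C010	disaccharide
COID000029	lactose		C010	disaccharide
COID000030	trehalose		C010	disaccharide
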