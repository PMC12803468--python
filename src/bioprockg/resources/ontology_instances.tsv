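coid	class_id
COID000001	C013
COID000002	C013
COID000003	C013
COID000004	C013
COID000005	C004
COID000006	C004
COID000007	C004
COID000008	C004
COID000009	C004
COID000010	C018
COID000011	C015
COID000012	C015
COID000013	C015
COID000014	C017
COID000015	C018
COID000016	C018
COID000017	C018
COID000018	C002
COID000019	C002
COID000020	C002
COID000021	C002
COID000022	C019
COID000023	C017
COID000024	C019
COID000025	C008
COID000026	C007
COID000027	C010
COID000028	C010
COID000029	C010
COID000030	C010
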