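child_id	relation	parent_id
C002	is_a	C001
C003	is_a	C002
C004	is_a	C003
C005	is_a	C001
C006	is_a	C005
C007	result	C001
C008	is_a	C020
C009	is_a	C008
C010	is_a	C009
C011	is_a	C008
C012	is_a	C011
C013	is_a	C008
C015	is_a	C014
C017	is_a	C016
C018	is_a	C016
C019	is_a	C016
C021	catalyst	C001
C022	role	C015
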