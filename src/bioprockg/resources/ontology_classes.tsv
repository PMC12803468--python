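class_id	name
C001	metabolic pathways
C002	biological processes
C003	PTM
C004	glycosylation
C005	substrates
C006	nucleotide or nucleoside
C007	by-product or waste
C008	secondary raw materials
C009	carbon sources
C010	disaccharide
C011	substitution material
C012	serum or serum replacements
C013	trace metals or minerals
C014	process parameters
C015	bioreactor conditions
C016	product outcomes
C017	product quality attributes
C018	clinical outcomes
C019	process performance
C020	raw materials
C021	enzymes
C022	buffers
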