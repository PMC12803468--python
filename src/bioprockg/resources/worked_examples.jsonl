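{"doc_id": "30682623", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "N-linked glycosylation affects the potency, safety, immunogenicity, and pharmacokinetic clearance of several therapeutic proteins including monoclonal antibodies."]]}
{"doc_id": "33656168", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "This slightly higher by-product formation for the on-demand cultures resulted most likely from the marginally higher VCD which was caused by the more concentrated on-demand medium."]]}
{"doc_id": "34289087", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "The subsequent systematic analysis of multi-omics data showed that pH set points differentially regulated various intracellular pathways including intracellular vesicular trafficking, cell cycle, and apoptosis, thereby resulting in differences in specific productivity, product titer, and quality profiles."]]}
{"doc_id": "33804825", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "It has also been reported that elevated osmolality is associated with an increased apoptosis rate, although early apoptosis markers were not examined in this study. In principle, elevated ammonia levels result in increased intracellular pH conditions that inhibit b4GalT activity and expression, and consequently lead to reduced protein galactosylation. As shown in Figure 6, the highest osmolality condition (500 mOsm kg-1 Feed C) has significantly lower levels of core fucosylation than the 410 mOsm kg-1 Feed C samples (p<0.05), despite having a lower specific antibody productivity."]]}
{"doc_id": "30597531", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "Using a small-scale (3 L) bioreactor model that can modulate pCO2 levels through modified configurations and gassing strategies, we identified three cell culture process parameters that influence afucosylation of a mAb produced by a recombinant Chinese Hamster Ovary (CHO) cell line: pCO2, media hold duration (at 37°C), and manganese. The extent of afucosylation, which refers to the absence of core fucose on Fc glycans, can correlate positively with the antibody-dependent cellular cytotoxicity (ADCC) activity of a monoclonal antibody (mAb)."]]}
{"doc_id": "35737825", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "Cell death in bioreactors reduces productivity and product quality, and is largely attributed to apoptosis."]]}
{"doc_id": "31487120", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "PCA was performed to assess the suitability of using MVDA to characterize the impact of media selection on antibody glycosylation and productivity."]]}
{"doc_id": "27752770", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "No effects of culture pH on qp could be shown in studies from Trummer et al. and Yoon et al.."]]}
{"doc_id": "25875452", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "This increased sialylation was enabled by a high level of galactosylation compared to the wild-type antibody."]]}
{"doc_id": "20639190", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "Antibodies lacking core fucosylation show a significantly enhanced antibody-dependent cell-mediated cytotoxicity (ADCC) and an increased efficacy of anti-tumor activity."]]}
{"doc_id": "30552760", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "Combinations of cytidine (Cyt), fucose (Fuc), and uridine, as well as sole addition of manganese chloride (Mn) or a mixture of Mn and galactose (Gal) with or without uridine, increased galactosylation (Fig. 5) without affecting negatively IVC or titer. Likewise, after the addition of compounds to increase sialylation (750 μM DANA, 50 mM ManNAc, 5 mg/ml fetuin, 0.5 mM CuCl2 on Day 8, and 30 μM dexamethasone), sialylated species were mainly found on the Fab fragment, and a maximum of approximately 2% Fc sialylation was observed."]]}
{"doc_id": "31544815", "doc_kind": "article", "chapter_number": null, "sections": [["Results", "The reduction of core fucosylation in the Fc-part of antibodies leads to enhanced ADCC and is therefore the aim of several investigations in the literature."]]}
{"doc_id": "99000001", "doc_kind": "abstract", "chapter_number": null, "sections": [["Abstract", "Nickel supplementation increased the galactosylation of a recombinant monoclonal antibody. Likewise, iron addition enhanced sialylation in fed-batch cultures."]]}
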