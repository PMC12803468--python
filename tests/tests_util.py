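"""Small helpers shared by test modules."""


def make_pred(doc_id, affector, affected, rtype, lexicon=None):
    """A prediction record as consumed by score_relations.

    Without a lexicon the concept columns carry the casefolded terms,
    matching the scorer's fallback normalization.
    """
    def cid(term):
        if lexicon is not None:
            hit = lexicon.lookup(term)
            if hit is not None:
                return hit.coid
        return term.casefold().strip()

    return {
        "doc_id": doc_id,
        "affector_coid": cid(affector),
        "affected_coid": cid(affected),
        "relation_type": rtype,
    }
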