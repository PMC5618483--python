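"""PROSITE signature matching and the screen / RBH / domain-check filters."""

import pytest

from snrkfam.align import ScoringScheme
from snrkfam.identify import (PrositeError, DomainSignature, domain_check,
                              load_signatures, prosite_to_regex,
                              reciprocal_best_hit, screen)
from snrkfam.simulate import ACT_SIG, ATP_SIG


# -- independent brute-force PROSITE matcher (no regex) -----------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _parse_tokens(pattern):
    toks = []
    for tok in pattern.strip().rstrip(".").strip("<>").split("-"):
        rep = (1, 1)
        if "(" in tok:
            tok, arg = tok.split("(")
            arg = arg.rstrip(")")
            rep = ((int(arg), int(arg)) if "," not in arg
                   else tuple(int(v) for v in arg.split(",")))
        if tok == "x":
            allowed = set(AA20) | {"X"}
        elif tok.startswith("["):
            allowed = set(tok[1:-1])
        elif tok.startswith("{"):
            allowed = (set(AA20) | {"X"}) - set(tok[1:-1])
        else:
            allowed = {tok}
        toks.append((allowed, rep))
    return toks


def brute_prosite_search(seq, pattern):
    """Leftmost match span (1-based inclusive) by explicit backtracking."""
    toks = _parse_tokens(pattern)

    def match_from(pos, t):
        if t == len(toks):
            return pos
        allowed, (lo, hi) = toks[t]
        # greedy from the minimum count upward; any success is a match
        for k in range(lo, hi + 1):
            if pos + k > len(seq):
                break
            if all(seq[pos + i] in allowed for i in range(k)):
                end = match_from(pos + k, t + 1)
                if end is not None:
                    return end
            else:
                break
        return None

    for start in range(len(seq)):
        end = match_from(start, 0)
        if end is not None:
            return (start + 1, end)
    return None


def test_simple_wildcard_pattern_span():
    sig = DomainSignature("toy", "A-x(2)-C")
    assert sig.search("AXXCDEF") == (1, 4)
    assert sig.search("GGAQQCG") == (3, 6)
    assert sig.search("AC") is None


@pytest.mark.parametrize("pattern", [
    "A-x(2)-C",
    "[LIV]-G-{P}-G",
    "D-[LIVMFY]-K-x(2)-N",
    "[LIVMFYC]-x-[HY]-x-D-[LIVMFY]-K-x(2)-N-[LIVMFYCT](3)",
    "G-x(1,3)-[DE]",
])
def test_matcher_agrees_with_brute_backtracking_oracle(pattern):
    import random
    rng = random.Random(11)
    sig = DomainSignature("toy", pattern)
    for _ in range(200):
        seq = "".join(rng.choice(AA20) for _ in range(rng.randint(4, 40)))
        assert sig.search(seq) == brute_prosite_search(seq, pattern), seq


def test_bundled_signatures_match_their_planted_instances():
    sigs = {s.name: s for s in load_signatures()}
    scaffold = "G" * 9 + ATP_SIG + "A" * 85 + ACT_SIG + "A" * 50
    ann = domain_check(scaffold, list(sigs.values()))
    assert ann.passed
    assert ann.spans["IPR017441"] == (10, 33)
    assert ann.spans["IPR008271"] == (119, 131)
    assert ann.table_style() == "IPR017441 (10-33); IPR008271 (119-131)"


def test_active_site_deleted_protein_fails():
    scaffold = "G" * 9 + ATP_SIG + "A" * 85 + "G" * len(ACT_SIG) + "A" * 50
    ann = domain_check(scaffold)
    assert not ann.passed
    assert ann.spans["IPR008271"] is None
    assert ann.spans["IPR017441"] == (10, 33)


def test_malformed_prosite_pattern_raises():
    with pytest.raises(PrositeError):
        prosite_to_regex("A-[B!]-C")
    with pytest.raises(PrositeError):
        prosite_to_regex("A--C")
    with pytest.raises(PrositeError):
        DomainSignature("bad", "Z-x").search("ACDE")


# -- screen and reciprocal best hit -------------------------------------


@pytest.fixture(scope="module")
def scheme():
    return ScoringScheme()


def _mutated(seq, positions, to="G"):
    chars = list(seq)
    for p in positions:
        chars[p] = to
    return "".join(chars)


def test_screen_retains_homolog_rejects_unrelated(scheme):
    import numpy as np
    rng = np.random.default_rng(3)
    aa = list(AA20)
    query = "".join(rng.choice(aa, 300))
    homolog = _mutated(query, rng.choice(300, 30, replace=False))
    unrelated = "".join(rng.choice(aa, 300))
    res = screen({"q": query}, {"hom": homolog, "rand": unrelated}, scheme)
    assert set(res.retained) == {"hom"}
    assert res.retained["hom"] == "q"
    assert set(res.hits.columns[:5]) == {"query", "target", "score",
                                         "bitscore", "evalue"}


def test_screen_validation(scheme):
    with pytest.raises(ValueError):
        screen({}, {"c": "ACDE"}, scheme)
    with pytest.raises(ValueError):
        screen({"q": "ACDE"}, {"c": "ACDE"}, scheme, threshold=0)


def test_rbh_rejects_candidate_closer_to_nonfamily(scheme):
    """A kinase-like candidate nearer a non-family reference is dropped even
    though it aligns to family queries."""
    import numpy as np
    rng = np.random.default_rng(4)
    aa = list(AA20)
    fam_ref = "".join(rng.choice(aa, 250))
    other_ref = _mutated(fam_ref, rng.choice(250, 100, replace=False))
    near_other = _mutated(other_ref, rng.choice(250, 12, replace=False))
    near_fam = _mutated(fam_ref, rng.choice(250, 12, replace=False))
    proteomes = {"SpA": {"fam1": fam_ref, "oth1": other_ref}}
    labels = {"fam1": True, "oth1": False}
    res = reciprocal_best_hit({"bad": near_other, "good": near_fam},
                              proteomes, labels, scheme)
    assert res.retained == ["good"]
    assert res.dropped == ["bad"]


def test_rbh_each_vs_any_species_mode(scheme):
    import numpy as np
    rng = np.random.default_rng(5)
    aa = list(AA20)
    fam = "".join(rng.choice(aa, 200))
    other = "".join(rng.choice(aa, 200))
    cand = _mutated(fam, rng.choice(200, 10, replace=False))
    proteomes = {
        "SpA": {"famA": fam, "othA": other},
        # in species B the family member is missing; best hit is non-family
        "SpB": {"othB": _mutated(cand, rng.choice(200, 5, replace=False))},
    }
    labels = {"famA": True, "othA": False, "othB": False}
    each = reciprocal_best_hit({"c": cand}, proteomes, labels, scheme, "each")
    any_ = reciprocal_best_hit({"c": cand}, proteomes, labels, scheme, "any")
    assert each.retained == []
    assert any_.retained == ["c"]
    with pytest.raises(ValueError):
        reciprocal_best_hit({"c": cand}, proteomes, labels, scheme, "both")
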