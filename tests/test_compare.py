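import functools

import numpy as np
import pytest

from varmotif.compare import (
    GAP_EXTEND,
    GAP_OPEN,
    PAIR_BONUS,
    Thresholds,
    element_presence,
    find_discriminating_features,
    identity_contrast,
    map_columns,
    mapping_score,
    profile_match_score,
    subset_by_gene,
)
from varmotif.consensus import ColumnProfile, build_consensus
from varmotif.synth import default_profile, generate_motif_pair


def random_model(rng, n_cols, n_rows=12, paired_frac=0.0):
    from varmotif.io import MotifAlignment

    chars = np.array(list("ACGU"))
    mat = chars[rng.integers(0, 4, size=(n_rows, n_cols))]
    ss = ["."] * n_cols
    n_pairs = int(paired_frac * n_cols / 2)
    for k in range(n_pairs):
        ss[k] = "<"
        ss[n_cols - 1 - k] = ">"
    seqs = ["".join(r) for r in mat]
    aln = MotifAlignment(
        "rand", [f"s{i}" for i in range(n_rows)], seqs, "".join(ss)
    )
    return build_consensus(aln), aln


def oracle_map_score(model_a, model_b):
    """Independent top-down recursion over (i, j, previous-op) states."""
    n, m = model_a.n_cols, model_b.n_cols
    s = {
        (i, j): profile_match_score(
            model_a.profile(i), model_b.profile(j),
            model_a.is_paired(i), model_b.is_paired(j),
            PAIR_BONUS,
        )
        for i in range(1, n + 1)
        for j in range(1, m + 1)
    }

    @functools.lru_cache(maxsize=None)
    def best(i, j, prev):
        if i > n and j > m:
            return 0.0
        options = []
        if i <= n and j <= m:
            options.append(s[(i, j)] + best(i + 1, j + 1, "M"))
        if i <= n:
            cost = GAP_EXTEND if prev == "X" else GAP_OPEN
            options.append(cost + best(i + 1, j, "X"))
        if j <= m:
            cost = GAP_EXTEND if prev == "Y" else GAP_OPEN
            options.append(cost + best(i, j + 1, "Y"))
        return max(options)

    return best(1, 1, "start")


class TestMapColumns:
    def test_self_alignment_is_identity(self, motif_pair):
        aln_a, _, _ = motif_pair
        model = build_consensus(aln_a)
        cmap = map_columns(model, model)
        assert cmap.matches == tuple((c, c) for c in range(1, model.n_cols + 1))
        assert cmap.unmatched_a == () and cmap.unmatched_b == ()

    def test_inserted_hairpin_lands_in_unmatched(self, motif_pair):
        aln_a, aln_b, truth = motif_pair
        model_a = build_consensus(aln_a)
        model_b = build_consensus(aln_b)
        cmap = map_columns(model_a, model_b)
        lo, hi = truth["element"]["span"]
        assert cmap.unmatched_a == tuple(range(lo, hi + 1))
        assert cmap.unmatched_b == ()
        assert len(cmap.matches) == model_b.n_cols

    def test_matches_oracle_on_random_models(self, rng):
        """DP optimum equals an independent memoized recursion (<= 30 cols)."""
        for trial in range(6):
            na = int(rng.integers(4, 31))
            nb = int(rng.integers(4, 31))
            ma, _ = random_model(rng, na, paired_frac=0.3)
            mb, _ = random_model(rng, nb, paired_frac=0.3)
            assert mapping_score(ma, mb) == pytest.approx(
                oracle_map_score(ma, mb), abs=1e-9
            )

    def test_map_complete_and_monotone_on_unrelated_profiles(self, rng):
        ma, _ = random_model(rng, 18)
        mb, _ = random_model(rng, 25)
        cmap = map_columns(ma, mb)
        used_a = sorted([a for a, _ in cmap.matches] + list(cmap.unmatched_a))
        used_b = sorted([b for _, b in cmap.matches] + list(cmap.unmatched_b))
        assert used_a == list(range(1, 19))
        assert used_b == list(range(1, 26))


def make_profile(n=100, **freqs):
    """ColumnProfile from residue fractions (rest gaps)."""
    counts = {x: 0 for x in "ACGU"}
    total = 0
    for nt, f in freqs.items():
        counts[nt] = round(n * f)
        total += counts[nt]
    counts["-"] = n - total
    return ColumnProfile(counts, n)


class TestIdentityContrast:
    def test_strict_full_contrast(self):
        # always G in one motif, never in the other
        feat = identity_contrast(make_profile(G=1.0), make_profile(A=1.0))
        assert feat.grade == "strict"
        assert feat.contrast == pytest.approx(1.0)
        assert feat.nt in ("G", "A")

    def test_equal_profiles_none(self):
        p = make_profile(A=0.5, C=0.5)
        assert identity_contrast(p, p) is None

    def test_high_grade(self):
        feat = identity_contrast(
            make_profile(C=0.92, A=0.08), make_profile(C=0.08, A=0.92)
        )
        assert feat.grade == "high"
        assert feat.contrast == pytest.approx(0.84)

    def test_95_5_is_high_not_strict(self):
        feat = identity_contrast(
            make_profile(G=0.95, A=0.05), make_profile(G=0.05, A=0.95)
        )
        assert feat.grade == "high"


class TestElementPresence:
    def test_full_occupancy(self, make_aln):
        aln = make_aln(["ACGUACGUAC"] * 5, "..........")
        assert element_presence(aln, (2, 9)) == 1.0

    def test_all_gapped(self, make_aln):
        aln = make_aln(["AC--------"] * 5, "..........")
        assert element_presence(aln, (3, 10)) == 0.0

    def test_min_residue_threshold(self, make_aln):
        aln = make_aln(["ACGUA-----", "ACGUACGU--"], "..........")
        # span 1-8: row1 has 5 residues (< 6), row2 has 8 (>= 6)
        assert element_presence(aln, (1, 8), min_residues=6) == 0.5


@pytest.fixture(scope="module")
def found():
    profile = default_profile()
    aln_a, aln_b, truth = generate_motif_pair(profile, 200, 200, seed=5)
    model_a = build_consensus(aln_a)
    model_b = build_consensus(aln_b)
    cmap = map_columns(model_a, model_b)
    feats = find_discriminating_features(aln_a, aln_b, model_a, model_b, cmap)
    return feats, truth


class TestFindDiscriminatingFeatures:
    def test_planted_features_recovered_strict(self, found):
        feats, truth = found
        strict = [f for f in feats if f.grade == "strict"]
        id_locs = {
            f.location for f in strict if f.kind == "identity_contrast"
        }
        assert id_locs == {
            (c["col_a"], c["col_b"]) for c in truth["contrasts"]
        }
        elems = [f for f in strict if f.kind == "element_presence"]
        assert len(elems) == 1
        assert elems[0].location == ("A", *truth["element"]["span"])

    def test_no_strict_false_positives(self, found):
        feats, truth = found
        strict = [f for f in feats if f.grade == "strict"]
        assert len(strict) == len(truth["contrasts"]) + 1

    def test_null_pair_has_no_strict_features(self):
        """Two samples of one profile (no planted differences) yield no
        strict contrasts."""
        from dataclasses import replace

        profile = replace(
            default_profile(), planted_contrasts=(), element=None
        )
        for seed in (21, 22, 23):
            aln_a, aln_b, _ = generate_motif_pair(profile, 200, 200, seed=seed)
            model_a = build_consensus(aln_a)
            model_b = build_consensus(aln_b)
            cmap = map_columns(model_a, model_b)
            feats = find_discriminating_features(
                aln_a, aln_b, model_a, model_b, cmap
            )
            assert [f for f in feats if f.grade == "strict"] == []

    def test_symmetry_under_swap(self, motif_pair):
        aln_a, aln_b, _ = motif_pair
        model_a = build_consensus(aln_a)
        model_b = build_consensus(aln_b)
        fwd = find_discriminating_features(
            aln_a, aln_b, model_a, model_b, map_columns(model_a, model_b)
        )
        rev = find_discriminating_features(
            aln_b, aln_a, model_b, model_a, map_columns(model_b, model_a)
        )
        fwd_mirrored = {
            (f.kind, f.location, f.grade, round(f.contrast, 6))
            for f in (g.mirrored() for g in fwd)
        }
        rev_set = {
            (f.kind, f.location, f.grade, round(f.contrast, 6)) for f in rev
        }
        assert fwd_mirrored == rev_set

    def test_feature_count_monotone_in_tau_hi(self, motif_pair):
        aln_a, aln_b, _ = motif_pair
        model_a = build_consensus(aln_a)
        model_b = build_consensus(aln_b)
        cmap = map_columns(model_a, model_b)
        counts = []
        for tau_hi in (0.85, 0.90, 0.97, 1.0):
            th = Thresholds(tau_hi=tau_hi, tau_hi2=tau_hi)
            feats = find_discriminating_features(
                aln_a, aln_b, model_a, model_b, cmap, thresholds=th
            )
            counts.append(len(feats))
        assert counts == sorted(counts, reverse=True)

    def test_high_not_strict_for_95_5_contrast(self):
        from dataclasses import replace

        from varmotif.synth import PlantedContrast

        base = default_profile()
        profile = replace(
            base,
            planted_contrasts=(
                PlantedContrast(20, "U", "G", freq_hi=0.95, freq_lo=0.05),
            ),
            element=None,
        )
        aln_a, aln_b, truth = generate_motif_pair(profile, 400, 400, seed=9)
        model_a = build_consensus(aln_a)
        model_b = build_consensus(aln_b)
        cmap = map_columns(model_a, model_b)
        feats = find_discriminating_features(aln_a, aln_b, model_a, model_b, cmap)
        at_20 = [f for f in feats if f.location == (20, 20)]
        assert len(at_20) == 1
        assert at_20[0].grade == "high"


class TestSubsetByGene:
    def test_filter_by_domain(self, make_aln):
        meta = {f"s{i}": {"gene_domain": "PRK07324" if i <= 6 else "MATE"}
                for i in range(1, 11)}
        aln = make_aln(
            [(f"s{i}", "ACGU") for i in range(1, 11)], "....", metadata=meta
        )
        out = subset_by_gene(aln, "prk07324")
        assert out.n_rows == 6

    def test_absent_domain_warns_and_empty(self, make_aln, caplog):
        meta = {"s1": {"gene_domain": "MATE"}}
        aln = make_aln([("s1", "ACGU")], "....", metadata=meta)
        with caplog.at_level("WARNING"):
            out = subset_by_gene(aln, "PRK07324")
        assert out.n_rows == 0
        assert "no rows match" in caplog.text

    def test_no_labels_raises(self, make_aln):
        aln = make_aln(["ACGU"], "....")
        with pytest.raises(ValueError):
            subset_by_gene(aln, "PRK07324")

    def test_subset_then_consensus_recovers_subset_conservation(self, profile):
        """Rows sharing the hallmark gene still carry the planted motif
        conservation after filtering (the subset-controlled comparison)."""
        aln_a, _, truth = generate_motif_pair(profile, 400, 100, seed=13)
        sub = subset_by_gene(aln_a, "PRK07324")
        assert sub.n_rows > 150
        model = build_consensus(sub)
        for c in truth["contrasts"]:
            nt, frac = model.profile(c["col_a"]).majority
            assert nt == c["nt_a"]
            assert frac == pytest.approx(1.0)
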