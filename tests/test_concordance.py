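"""Concordance-filter tests: hand-built toy matrices, an independent
brute-force rule oracle on random matrices, and the panel screen."""

import numpy as np
import pandas as pd
import pytest

from magicmap.concordance import (
    HETEROGENEOUS,
    MUTANT,
    PERMISSIVE,
    STRICT,
    WILD_TYPE,
    FilterConfig,
    concordance_filter,
    marker_concordance,
    screen_panel,
)
from magicmap.genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from magicmap.popsim import PhenotypeTable


def build_matrix(calls, sample_class, samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    samples = samples or [f"S{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": "D10",
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(
        sites, samples, calls, np.ones_like(calls, dtype=np.int32),
        dict(zip(samples, sample_class)),
    )


# ------------------------------------------------- independent rule oracle


def oracle_filter(matrix, phenotypes, sensitive_parent, config):
    """Literal per-site re-evaluation of rules (a)-(d) with loops."""
    sp = matrix.sample_index(sensitive_parent)
    permissive = config.mode == PERMISSIVE
    other_parents = [
        matrix.sample_index(s)
        for s in matrix.samples
        if matrix.sample_class.get(s) == "parent" and s != sensitive_parent
    ]
    lines = [s for s in matrix.samples if matrix.sample_class.get(s) != "parent"]
    sens = [matrix.sample_index(s) for s in lines if phenotypes.labels.get(s) == "sensitive"]
    tol = [matrix.sample_index(s) for s in lines if phenotypes.labels.get(s) == "tolerant"]

    keep = []
    for i in range(matrix.n_sites):
        row = matrix.calls[i]
        if config.region is not None:
            chrom, start, end = config.region
            site = matrix.sites.iloc[i]
            if site["chrom"] != chrom or not (start <= site["pos"] <= end):
                continue
        if row[sp] != HOM_ALT:
            continue
        ok = True
        for j in other_parents:
            if row[j] == HOM_REF or (permissive and row[j] == MISSING):
                continue
            ok = False
        for j in sens:
            if row[j] == HOM_ALT or (permissive and row[j] == MISSING):
                continue
            ok = False
        if config.require_tolerant_exclusion:
            for j in tol:
                if row[j] == HOM_ALT:
                    ok = False
                if not permissive and row[j] == MISSING:
                    ok = False
        if ok:
            keep.append(i)
    return keep


def random_matrix(rng, n_sites=50, n_samples=20):
    calls = rng.choice(
        [HOM_REF, HET, HOM_ALT, MISSING], size=(n_sites, n_samples),
        p=[0.45, 0.15, 0.25, 0.15],
    )
    classes = ["parent"] * 4 + ["RIL"] * (n_samples - 4)
    m = build_matrix(calls, classes)
    labels = {
        s: ("sensitive" if rng.random() < 0.3 else "tolerant")
        for s in m.samples[4:]
    }
    # guarantee at least one sensitive line
    labels[m.samples[4]] = "sensitive"
    return m, PhenotypeTable(labels)


class TestConcordanceFilter:
    def test_planted_causal_site_retained(self):
        # parent0 sensitive parent hom-alt; parents 1-2 hom-ref;
        # sensitive lines hom-alt, tolerant lines hom-ref
        calls = [
            [HOM_ALT, HOM_REF, HOM_REF, HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],  # causal
            [HOM_ALT, HOM_REF, HOM_REF, HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],  # perfect LD
            [HOM_REF, HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_ALT, HOM_ALT],  # wrong parent
        ]
        m = build_matrix(calls, ["parent"] * 3 + ["RIL"] * 4)
        ph = PhenotypeTable(
            {
                "S3": "sensitive", "S4": "sensitive",
                "S5": "tolerant", "S6": "tolerant",
            }
        )
        cands = concordance_filter(m, ph, "S0")
        assert [p for _, p in cands.positions()] == [100, 200]

    def test_sensitive_hom_ref_excludes_site(self):
        calls = [[HOM_ALT, HOM_REF, HOM_REF, HOM_ALT]]
        m = build_matrix(calls, ["parent", "parent", "RIL", "RIL"])
        ph = PhenotypeTable({"S2": "sensitive", "S3": "sensitive"})
        assert len(concordance_filter(m, ph, "S0")) == 0

    def test_sensitive_het_always_disqualifies(self):
        calls = [[HOM_ALT, HOM_REF, HET, HOM_ALT]]
        m = build_matrix(calls, ["parent", "parent", "RIL", "RIL"])
        ph = PhenotypeTable({"S2": "sensitive", "S3": "sensitive"})
        for mode in (PERMISSIVE, STRICT):
            assert len(concordance_filter(m, ph, "S0", FilterConfig(mode))) == 0

    def test_toy_matrix_equals_rule_by_rule_oracle(self):
        # 6 samples (2 parents, 2 sensitive, 2 tolerant), 5 sites with
        # hand-chosen calls including missing data
        calls = [
            [HOM_ALT, HOM_REF, HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],  # pass
            [HOM_ALT, MISSING, HOM_ALT, MISSING, HOM_REF, HET],      # permissive-only
            [HOM_ALT, HOM_REF, HOM_ALT, HOM_ALT, HOM_ALT, HOM_REF],  # tolerant hom-alt
            [HOM_REF, HOM_REF, HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],  # parent not alt
            [HOM_ALT, HET, HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],      # other parent het
        ]
        m = build_matrix(calls, ["parent", "parent", "RIL", "RIL", "RIL", "RIL"])
        ph = PhenotypeTable(
            {
                "S2": "sensitive", "S3": "sensitive",
                "S4": "tolerant", "S5": "tolerant",
            }
        )
        for mode in (PERMISSIVE, STRICT):
            config = FilterConfig(mode)
            got = [m.site_index("D10", p) for _, p in
                   concordance_filter(m, ph, "S0", config).positions()]
            assert got == oracle_filter(m, ph, "S0", config)
        # spot-check the hand expectation too
        perm = concordance_filter(m, ph, "S0", FilterConfig(PERMISSIVE))
        strict = concordance_filter(m, ph, "S0", FilterConfig(STRICT))
        assert [p for _, p in perm.positions()] == [100, 200]
        assert [p for _, p in strict.positions()] == [100]

    @pytest.mark.parametrize("trial", range(25))
    def test_oracle_equivalence_random_matrices(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m, ph = random_matrix(rng)
        for mode in (PERMISSIVE, STRICT):
            for excl in (True, False):
                config = FilterConfig(mode, require_tolerant_exclusion=excl)
                got = [m.site_index(c, p) for c, p in
                       concordance_filter(m, ph, "S0", config).positions()]
                assert got == oracle_filter(m, ph, "S0", config)

    @pytest.mark.parametrize("trial", range(10))
    def test_strict_subset_of_permissive(self, trial):
        rng = np.random.default_rng(2000 + trial)
        m, ph = random_matrix(rng)
        strict = set(concordance_filter(m, ph, "S0", FilterConfig(STRICT)).positions())
        perm = set(concordance_filter(m, ph, "S0", FilterConfig(PERMISSIVE)).positions())
        assert strict <= perm

    def test_adding_tolerant_hom_alt_never_adds_candidates(self):
        rng = np.random.default_rng(7)
        m, ph = random_matrix(rng)
        base = set(concordance_filter(m, ph, "S0").positions())
        # append one tolerant line that is hom-alt everywhere
        calls2 = np.column_stack([m.calls, np.full(m.n_sites, HOM_ALT, np.int8)])
        classes2 = [m.sample_class[s] for s in m.samples] + ["RIL"]
        m2 = build_matrix(calls2, classes2, samples=m.samples + ["EXTRA"])
        ph2 = PhenotypeTable({**ph.labels, "EXTRA": "tolerant"})
        after = set(concordance_filter(m2, ph2, "S0").positions())
        assert after <= base

    def test_region_restriction(self):
        calls = [[HOM_ALT, HOM_REF, HOM_ALT]] * 4
        m = build_matrix(calls, ["parent", "parent", "RIL"])
        ph = PhenotypeTable({"S2": "sensitive"})
        config = FilterConfig(region=("D10", 150, 350))
        got = concordance_filter(m, ph, "S0", config).positions()
        assert [p for _, p in got] == [200, 300]

    def test_missing_sensitive_parent_rejected(self):
        m = build_matrix([[HOM_ALT, HOM_ALT]], ["parent", "RIL"])
        ph = PhenotypeTable({"S1": "sensitive"})
        with pytest.raises(ValueError, match="not in matrix"):
            concordance_filter(m, ph, "NOPE")

    def test_no_sensitive_samples_rejected(self):
        m = build_matrix([[HOM_ALT, HOM_ALT]], ["parent", "RIL"])
        ph = PhenotypeTable({"S1": "tolerant"})
        with pytest.raises(ValueError, match="no sensitive"):
            concordance_filter(m, ph, "S0")

    def test_evidence_tallies(self):
        calls = [[HOM_ALT, MISSING, HOM_ALT, MISSING, HET]]
        m = build_matrix(calls, ["parent", "parent", "RIL", "RIL", "RIL"])
        ph = PhenotypeTable({"S2": "sensitive", "S3": "sensitive", "S4": "tolerant"})
        cands = concordance_filter(m, ph, "S0", FilterConfig(PERMISSIVE))
        row = cands.table.iloc[0]
        assert row["n_sensitive_hom_alt"] == 1
        assert row["n_missing"] == 2
        assert row["n_tolerant_hom_alt"] == 0


class TestMarkerConcordance:
    def test_perfect_cosegregation_zero_discordant(self):
        calls = np.array([HOM_ALT, HOM_ALT, HET, HOM_REF])
        ids = ["a", "b", "c", "d"]
        ph = PhenotypeTable(
            {"a": "sensitive", "b": "sensitive", "c": "tolerant", "d": "tolerant"}
        )
        rep = marker_concordance(calls, ids, ph)
        assert rep.n_discordant == 0
        assert rep.n_missing == 0

    def test_sensitive_het_is_discordant(self):
        ph = PhenotypeTable({"a": "sensitive"})
        rep = marker_concordance(np.array([HET]), ["a"], ph)
        assert rep.n_discordant == 1

    def test_tolerant_hom_alt_is_discordant(self):
        ph = PhenotypeTable({"a": "tolerant"})
        rep = marker_concordance(np.array([HOM_ALT]), ["a"], ph)
        assert rep.n_discordant == 1

    def test_all_missing(self):
        ph = PhenotypeTable({"a": "sensitive", "b": "tolerant"})
        rep = marker_concordance(np.array([MISSING, MISSING]), ["a", "b"], ph)
        assert rep.n_discordant == 0
        assert rep.n_missing == 2

    def test_unknown_model_rejected(self):
        ph = PhenotypeTable({"a": "tolerant"})
        with pytest.raises(ValueError, match="model"):
            marker_concordance(np.array([HOM_REF]), ["a"], ph, model="overdominant")

    def test_counts_table_totals(self):
        calls = np.array([HOM_REF, HET, HOM_ALT, MISSING, HOM_ALT])
        ids = list("abcde")
        ph = PhenotypeTable(
            {
                "a": "tolerant", "b": "tolerant", "c": "sensitive",
                "d": "sensitive", "e": "sensitive",
            }
        )
        rep = marker_concordance(calls, ids, ph)
        assert rep.counts.to_numpy().sum() == 5
        assert rep.counts.loc["hom_alt", "sensitive"] == 2


class TestScreenPanel:
    def test_all_hom_alt_is_mutant(self):
        status = screen_panel(
            np.array([HOM_ALT, HOM_ALT]), ["s1", "s2"], {"s1": "cv1", "s2": "cv1"}
        )
        assert status == {"cv1": MUTANT}

    def test_mixed_calls_heterogeneous(self):
        status = screen_panel(
            np.array([HOM_ALT, HOM_REF]), ["s1", "s2"], {"s1": "cv1", "s2": "cv1"}
        )
        assert status == {"cv1": HETEROGENEOUS}

    def test_het_call_heterogeneous(self):
        status = screen_panel(np.array([HET]), ["s1"], {"s1": "cv1"})
        assert status == {"cv1": HETEROGENEOUS}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            screen_panel(np.array([]), [], {})

    def test_synthetic_panel_recovers_planted_mutants(self):
        # 384 cultivars, 10 pooled seedlings each, 12 planted mutant cultivars
        rng = np.random.default_rng(42)
        n_cultivars, pool = 384, 10
        mutants = set(rng.choice(n_cultivars, size=12, replace=False).tolist())
        calls, ids, cultivar_of = [], [], {}
        for c in range(n_cultivars):
            for s in range(pool):
                sid = f"cv{c:03d}_s{s}"
                ids.append(sid)
                cultivar_of[sid] = f"cv{c:03d}"
                calls.append(HOM_ALT if c in mutants else HOM_REF)
        status = screen_panel(np.array(calls), ids, cultivar_of)
        flagged = {c for c, st in status.items() if st == MUTANT}
        assert flagged == {f"cv{c:03d}" for c in mutants}
        assert len(flagged) == 12
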