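"""GY94 machinery, site models, ancestral codons and change counting."""

import numpy as np
import pytest

from collemsel.codes import get_code
from collemsel.codon_selection import (CodonModelParams, branch_change_table,
                                       branch_id, branch_omega,
                                       codon_log_likelihood, complex_summary,
                                       f3x4_frequencies, fit_site_model,
                                       gene_site_counts, gy94_rate_matrix,
                                       reconstruct_ancestral_codons, site_lrt,
                                       standardized_gene_pct, _CodonEig)
from collemsel.phylo_io import CodonAlignment, parse_tree
from collemsel.synthetic_data import simulate_bd_tree, simulate_codon_alignment

N_SENSE = 62


def uniform_pi():
    return np.full(N_SENSE, 1.0 / N_SENSE)


def random_pi(rng):
    return rng.dirichlet(np.full(N_SENSE, 5.0))


class TestGy94Matrix:
    def test_rows_sum_to_zero(self):
        Q = gy94_rate_matrix(2.0, 0.5, uniform_pi())
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = random_pi(rng)
        Q = gy94_rate_matrix(3.0, 0.7, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_normalised_to_unit_mean_rate(self):
        pi = uniform_pi()
        Q = gy94_rate_matrix(2.0, 0.5, pi)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_only_single_nucleotide_moves(self):
        code = get_code(5)
        Q = gy94_rate_matrix(2.0, 0.5, uniform_pi())
        sense = code.sense_codons
        for i in range(0, N_SENSE, 7):
            for j in range(0, N_SENSE, 11):
                if i == j:
                    continue
                ndiff = sum(a != b for a, b in zip(sense[i], sense[j]))
                if ndiff > 1:
                    assert Q[i, j] == 0.0

    def test_eigendecomposition_matches_expm(self):
        from scipy.linalg import expm
        rng = np.random.default_rng(1)
        pi = random_pi(rng)
        Q = gy94_rate_matrix(2.5, 0.3, pi)
        eig = _CodonEig(Q, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(eig.P(t), expm(Q * t), atol=1e-9)


class TestCodonPruning:
    def test_matches_enumeration_three_taxa(self):
        # oracle: explicit sum over root and internal codon states
        code = get_code(5)
        idx = code.codon_index
        rng = np.random.default_rng(2)
        for case in range(50):
            kappa = rng.uniform(0.5, 8.0)
            omega = rng.uniform(0.05, 3.0)
            pi = random_pi(rng)
            ta, tb, tc, tab = rng.uniform(0.02, 0.8, 4)
            tree = parse_tree(f"((A:{ta},B:{tb}):{tab},C:{tc});")
            Q = gy94_rate_matrix(kappa, omega, pi)
            eig = _CodonEig(Q, pi)
            n_sites = 3
            sense = code.sense_codons
            cods = rng.integers(0, N_SENSE, size=(3, n_sites))
            aln = CodonAlignment("g", {
                "A": "".join(sense[i] for i in cods[0]),
                "B": "".join(sense[i] for i in cods[1]),
                "C": "".join(sense[i] for i in cods[2])}, code)
            params = CodonModelParams(kappa, (omega,), (1.0,), pi)
            ll = codon_log_likelihood(tree, aln, params)
            # brute force
            Pa, Pb, Pc, Pab = (eig.P(t) for t in (ta, tb, tc, tab))
            total = 0.0
            for s in range(n_sites):
                a, b, c = cods[:, s]
                inner = (Pab @ (Pa[:, a] * Pb[:, b]))
                total += np.log((pi * inner * Pc[:, c]).sum())
            assert ll == pytest.approx(total, rel=1e-8)

    def test_mixture_single_class_equals_m0(self):
        tree = simulate_bd_tree(5, 1.0, 0.0, 1.0, seed=3)
        sim = simulate_codon_alignment(tree, 40, omega=0.4, rate_scale=0.3,
                                       seed=4)
        pi = f3x4_frequencies(sim.alignment)
        m0 = CodonModelParams(2.0, (0.4,), (1.0,), pi, 5, 0.3)
        mix = CodonModelParams(2.0, (0.4, 0.4, 0.4), (0.2, 0.5, 0.3), pi,
                               5, 0.3)
        assert codon_log_likelihood(tree, sim.alignment, m0) == pytest.approx(
            codon_log_likelihood(tree, sim.alignment, mix), rel=1e-9)


class TestAncestralReconstruction:
    def test_invariant_site_propagates(self):
        code = get_code(5)
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment("g", {t: "ATGAAA" for t in "ABC"}, code)
        params = CodonModelParams(2.0, (0.5,), (1.0,), uniform_pi())
        anc = reconstruct_ancestral_codons(tree, aln, params)
        for nd in tree.postorder_nodes:
            assert anc.sequences[nd] == ["ATG", "AAA"]
            if not nd.is_leaf:
                assert np.all(anc.posterior[nd] > 0.95)

    def test_two_tip_ancestor_closed_form(self):
        # ancestor posterior proportional to pi-weighted transition products
        code = get_code(5)
        rng = np.random.default_rng(5)
        pi = random_pi(rng)
        kappa, omega, t1, t2 = 2.0, 0.5, 0.15, 0.4
        tree = parse_tree(f"(A:{t1},B:{t2});")
        ca, cb = "TTT", "TTA"
        aln = CodonAlignment("g", {"A": ca, "B": cb}, code)
        params = CodonModelParams(kappa, (omega,), (1.0,), pi)
        anc = reconstruct_ancestral_codons(tree, aln, params)
        Q = gy94_rate_matrix(kappa, omega, pi)
        eig = _CodonEig(Q, pi)
        Pa, Pb = eig.P(t1), eig.P(t2)
        ia, ib = code.codon_index[ca], code.codon_index[cb]
        marg = pi * Pa[:, ia] * Pb[:, ib]
        marg /= marg.sum()
        best = int(np.argmax(marg))
        root = tree.root
        assert anc.sequences[root][0] == code.sense_codons[best]
        assert anc.posterior[root][0] == pytest.approx(marg[best], rel=1e-9)

    def test_accuracy_at_low_divergence(self):
        # >= 90% of internal states correct when branches are short
        tree = simulate_bd_tree(8, 1.0, 0.0, 1.0, seed=6)
        sim = simulate_codon_alignment(tree, 300, kappa=2.0, omega=0.3,
                                       rate_scale=0.3, seed=7)
        params = CodonModelParams(2.0, (0.3,), (1.0,), uniform_pi(), 5, 0.3)
        anc = reconstruct_ancestral_codons(tree, sim.alignment, params)
        correct = total = 0
        for nd in tree.postorder_nodes:
            if nd.is_leaf:
                continue
            for truth, est in zip(sim.node_sequences[nd], anc.sequences[nd]):
                total += 1
                correct += (truth == est)
        assert correct / total >= 0.90

    def test_masked_column_left_unreconstructed(self):
        code = get_code(5)
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment("g", {"A": "ATG---", "B": "ATGAAA",
                                   "C": "ATGAAA"}, code)
        params = CodonModelParams(2.0, (0.5,), (1.0,), uniform_pi())
        anc = reconstruct_ancestral_codons(tree, aln, params)
        assert anc.sequences[tree.root][1] is None


class TestBranchCounting:
    def test_identical_sequences_zero_counts(self):
        code = get_code(5)
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment("g", {t: "ATGAAATTT" for t in "ABC"}, code)
        params = CodonModelParams(2.0, (0.5,), (1.0,), uniform_pi())
        anc = reconstruct_ancestral_codons(tree, aln, params)
        bct = branch_change_table(tree, anc)
        assert (bct.table[["dN", "dS"]].to_numpy() == 0).all()

    def test_omega_zero_means_no_nonsynonymous(self):
        tree = simulate_bd_tree(6, 1.0, 0.0, 1.0, seed=8)
        sim = simulate_codon_alignment(tree, 150, omega=0.0, rate_scale=0.5,
                                       seed=9)
        # the truth has no nonsynonymous events at all
        assert all(n == 0 for _, n in sim.branch_counts.values())
        params = CodonModelParams(2.0, (1e-4,), (1.0,), uniform_pi(), 5, 0.5)
        anc = reconstruct_ancestral_codons(tree, sim.alignment, params)
        bct = branch_change_table(tree, anc)
        # counting on reconstructed states stays essentially synonymous
        assert bct.table["dN"].sum() <= 0.02 * bct.table["dS"].sum()

    def test_counts_track_simulated_events(self):
        # per-branch totals match the recorded event log at low divergence
        tree = simulate_bd_tree(8, 1.0, 0.0, 1.0, seed=10)
        sim = simulate_codon_alignment(tree, 400, kappa=2.0, omega=0.5,
                                       rate_scale=0.25, seed=11)
        params = CodonModelParams(2.0, (0.5,), (1.0,), uniform_pi(), 5, 0.25)
        anc = reconstruct_ancestral_codons(tree, sim.alignment, params)
        bct = branch_change_table(tree, anc)
        est = bct.table.set_index("branch")
        devs = []
        for br, (syn, nonsyn) in sim.branch_counts.items():
            true_total = syn + nonsyn
            got = est.loc[br, "dN"] + est.loc[br, "dS"]
            devs.append(abs(got - true_total) / max(true_total, 1.0))
        assert np.median(devs) <= 0.10

    def test_omega_recovery_band(self):
        # counting-based omega for true omega 0.2 lands in [0.1, 0.35]
        tree = simulate_bd_tree(8, 1.0, 0.0, 1.0, seed=12)
        sim = simulate_codon_alignment(tree, 500, kappa=2.0, omega=0.2,
                                       rate_scale=0.3, seed=13)
        fit = fit_site_model(tree, sim.alignment, "M0", n_starts=2, tol=1e-6)
        anc = reconstruct_ancestral_codons(tree, sim.alignment, fit.params)
        bct = branch_change_table(tree, anc)
        S, N = gene_site_counts(sim.alignment)
        tot = bct.table[["dN", "dS"]].sum()
        omega_hat = branch_omega(tot["dN"], tot["dS"], N, S)
        assert 0.1 <= omega_hat <= 0.35


class TestBranchOmega:
    def test_zero_nonsynonymous(self):
        assert branch_omega(0.0, 5.0, 300.0, 100.0) == 0.0

    def test_equal_per_site_rates_give_one(self):
        # dN/N == dS/S -> omega = 1
        assert branch_omega(6.0, 2.0, 300.0, 100.0) == pytest.approx(1.0)

    def test_undefined_without_synonymous_changes(self):
        assert branch_omega(3.0, 0.0, 300.0, 100.0) is None

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            branch_omega(1.0, 1.0, 0.0, 100.0)


class TestSiteCounts:
    def test_per_codon_bounds(self):
        code = get_code(5)
        aln = CodonAlignment("g", {"A": "ATGAAATTTGGA"}, code)
        S, N = gene_site_counts(aln)
        assert S + N <= 12.0 + 1e-9
        assert S > 0 and N > 0


class TestStandardisedPercent:
    def test_printed_formula(self):
        assert standardized_gene_pct(6, 100, 3) == pytest.approx(2.0)

    def test_zero_changes(self):
        assert standardized_gene_pct(0, 100, 3) == 0.0

    def test_doubling_invariance(self):
        a = standardized_gene_pct(6, 100, 3)
        b = standardized_gene_pct(12, 100, 6)
        assert a == pytest.approx(b)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            standardized_gene_pct(6, 0, 3)


class TestComplexSummary:
    def _table(self, counts):
        import pandas as pd
        from collemsel.codon_selection import BranchChangeTable
        rows = [{"branch": f"b{i}", "gene": g, "dN": dn, "dS": ds,
                 "n_sites_used": 100}
                for g, per in counts.items()
                for i, (dn, ds) in enumerate(per)]
        return BranchChangeTable(pd.DataFrame(rows))

    def test_single_gene_per_complex_equals_gene_value(self):
        bct = self._table({"cytb": [(4, 2), (2, 2)]})
        out = complex_summary(bct, {"cytb": 100})
        gene = out.attrs["per_gene"]
        assert out.loc[0, "pct_nonsyn"] == pytest.approx(
            gene.loc[0, "pct_nonsyn"])

    def test_unmapped_gene_warns_and_excluded(self):
        bct = self._table({"cytb": [(4, 2)], "mystery": [(9, 0)]})
        with pytest.warns(UserWarning, match="mystery"):
            out = complex_summary(bct, {"cytb": 100, "mystery": 100})
        assert set(out["complex"]) == {"III"}

    def test_elevated_gene_ranks_its_complex_first(self):
        # strong excess of nonsynonymous changes on atp8 puts complex V first
        tree = simulate_bd_tree(8, 1.0, 0.0, 1.0, seed=14)
        genes = {"atp8": 3.0, "cytb": 0.2, "cox1": 0.2, "nad1": 0.2}
        ancs = []
        sizes = {}
        for g, om in genes.items():
            sim = simulate_codon_alignment(tree, 200, omega=om,
                                           rate_scale=0.3, seed=hash(g) % 100,
                                           gene_name=g)
            params = CodonModelParams(2.0, (om,), (1.0,), uniform_pi(), 5,
                                      0.3)
            ancs.append(reconstruct_ancestral_codons(tree, sim.alignment,
                                                     params))
            sizes[g] = 200
        bct = branch_change_table(tree, ancs)
        out = complex_summary(bct, sizes)
        assert out.loc[0, "complex"] == "V"


class TestSiteModels:
    def test_lrt_statistic_nonnegative_and_df2(self):
        tree = simulate_bd_tree(6, 1.0, 0.0, 1.0, seed=15)
        sim = simulate_codon_alignment(tree, 120, site_classes=((0.1, 1.0),
                                                                (0.7, 0.3)),
                                       rate_scale=0.4, seed=16)
        f1 = fit_site_model(tree, sim.alignment, "M1a", n_starts=2, tol=1e-6)
        f2 = fit_site_model(tree, sim.alignment, "M2a", n_starts=2,
                            init=f1, tol=1e-6)
        stat, df, p = site_lrt(f1, f2)
        assert stat >= 0 and df == 2 and 0 <= p <= 1
        assert f2.log_likelihood >= f1.log_likelihood - 1e-6

    def test_m2a_site_posteriors_in_unit_interval(self):
        tree = simulate_bd_tree(6, 1.0, 0.0, 1.0, seed=17)
        sim = simulate_codon_alignment(tree, 120,
                                       site_classes=((0.1, 1.0, 4.0),
                                                     (0.6, 0.25, 0.15)),
                                       rate_scale=0.4, seed=18)
        f2 = fit_site_model(tree, sim.alignment, "M2a", n_starts=2, tol=1e-6)
        post = f2.site_posterior
        assert post is not None and len(post) == 120
        assert np.nanmin(post) >= 0 and np.nanmax(post) <= 1
        # the 0.95 posterior threshold gates the site calls
        called = f2.positively_selected_sites(0.95)
        assert all(post[i] >= 0.95 for i in called)

    def test_unknown_model_rejected(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        aln = CodonAlignment("g", {t: "ATGAAA" for t in "ABC"}, get_code(5))
        with pytest.raises(ValueError):
            fit_site_model(tree, aln, "M8")
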