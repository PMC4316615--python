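import math
import subprocess

import numpy as np
import pytest

from retrochron.io import reverse_complement
from retrochron.landscape import (
    LandscapeInput,
    LandscapeTable,
    aligned_bp,
    compute_landscape,
    detect_extant_activity,
    k2p_distance,
)
from retrochron.simulate import SimConfig, SubfamilySpec, simulate_history
from retrochron.trees import read_newick


def oracle_k2p(copy_row, cons_row, exclude_cpg=True):
    """Independent vectorised K2P evaluation used to check the implementation."""
    a = np.frombuffer(copy_row.upper().encode(), dtype="S1")
    b = np.frombuffer(cons_row.upper().encode(), dtype="S1")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(a, acgt) & np.isin(b, acgt)
    if exclude_cpg:
        pos = np.flatnonzero(~np.isin(b, [b"-", b"N"]))
        cpg = np.zeros(len(b), dtype=bool)
        for x, y in zip(pos, pos[1:]):
            if b[x] == b"C" and b[y] == b"G":
                cpg[x] = cpg[y] = True
        valid &= ~cpg
    aa, bb = a[valid], b[valid]
    n = len(aa)
    diff = aa != bb
    purine = np.isin(aa, [b"A", b"G"]) == np.isin(bb, [b"A", b"G"])
    P = float(np.sum(diff & purine)) / n
    Q = float(np.sum(diff & ~purine)) / n
    return P, Q, -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


class TestK2P:
    def test_identical_sequences(self):
        est = k2p_distance("ACGTTT", "ACGTTT")
        assert (est.P, est.Q, est.d) == (0.0, 0.0, 0.0)

    def test_known_closed_form(self):
        # P = 0.1, Q = 0.05 over 100 CpG-free columns
        cons = "AT" * 50
        copy = list(cons)
        for i in range(0, 20, 2):
            copy[i] = "G"  # ten A->G transitions
        for i in range(1, 11, 2):
            copy[i] = "A"  # five T->A transversions
        est = k2p_distance("".join(copy), cons)
        assert est.P == pytest.approx(0.1)
        assert est.Q == pytest.approx(0.05)
        assert est.d == pytest.approx(0.17018, abs=5e-6)

    def test_cpg_confined_mismatches_give_zero(self):
        cons = "AACGAACGAACG"  # CpG at positions (2,3), (6,7), (10,11)
        copy = "AATAAATAAATA"  # mismatches only inside consensus CpG columns
        est = k2p_distance(copy, cons, exclude_cpg=True)
        assert est.d == 0.0
        assert est.compared_columns == 6

    def test_cpg_exclusion_never_increases_columns(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), size=300))
        incl = k2p_distance(s, s, exclude_cpg=False)
        excl = k2p_distance(s, s, exclude_cpg=True)
        assert excl.compared_columns <= incl.compared_columns

    def test_saturation_flagged(self):
        cons = "A" * 60
        copy = "G" * 60  # all transitions: P > 0.5
        est = k2p_distance(copy, cons)
        assert est.saturated and est.d == math.inf

    def test_zero_comparable_columns_is_error(self):
        with pytest.raises(ValueError):
            k2p_distance("---", "AC-")

    def test_symmetry_without_cpg_rule(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        assert k2p_distance(a, b, exclude_cpg=False).d == pytest.approx(
            k2p_distance(b, a, exclude_cpg=False).d
        )

    def test_agrees_with_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(60, 240))
            cons = "".join(rng.choice(list("ACGT"), size=n))
            copy = list(cons)
            for i in rng.choice(n, size=int(0.12 * n), replace=False):
                copy[i] = rng.choice([b for b in "ACGT" if b != copy[i]])
            est = k2p_distance("".join(copy), cons)
            P, Q, d = oracle_k2p("".join(copy), cons)
            assert est.P == pytest.approx(P, abs=1e-12)
            assert est.Q == pytest.approx(Q, abs=1e-12)
            assert est.d == pytest.approx(d, abs=1e-9)

    def test_agrees_with_ape_reference(self, tmp_path):
        """Cross-check the distance (CpG rule off) against R's ape::dist.dna."""
        rng = np.random.default_rng(9)
        cons = "".join(rng.choice(list("ACGT"), size=400))
        copy = list(cons)
        for i in rng.choice(400, size=40, replace=False):
            copy[i] = rng.choice([b for b in "ACGT" if b != copy[i]])
        copy = "".join(copy)
        script = tmp_path / "k80.R"
        script.write_text(
            'library(ape)\n'
            f'm <- rbind(strsplit("{copy.lower()}", "")[[1]],'
            f' strsplit("{cons.lower()}", "")[[1]])\n'
            'd <- dist.dna(as.DNAbin(m), model="K80")\n'
            'cat(sprintf("%.10f", as.numeric(d)))\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        est = k2p_distance(copy, cons, exclude_cpg=False)
        assert est.d == pytest.approx(float(out.stdout.strip()), abs=1e-8)


class TestBinning:
    def test_single_copy_bin_arithmetic(self):
        est = k2p_distance("ACGT" * 25, "ACGT" * 25)
        est.d, est.P = 0.124, 0.1  # place a 100-bp copy at 12.4% divergence
        table = compute_landscape(
            [LandscapeInput(est, "S", aligned_bp=100)], {"S": "E"}
        )
        assert table.bp[0, 12] == 100
        assert table.bp.sum() == 100

    def test_conservation_and_discards(self):
        ests = []
        for i, d in enumerate([0.01, 0.2, 0.49, 0.5, 0.6]):
            e = k2p_distance("AAAA", "AAAA", copy_id=f"c{i}")
            e.d = d
            ests.append(LandscapeInput(e, "S", aligned_bp=100))
        table = compute_landscape(ests, {"S": "E"})
        assert table.bp.sum() == 300  # d >= 0.5 discarded
        assert table.discarded_copies == 2
        assert table.discarded_bp == 200

    def test_unmapped_subfamily_is_error(self):
        est = k2p_distance("ACGT", "ACGT")
        with pytest.raises(ValueError, match="nowhere"):
            compute_landscape([LandscapeInput(est, "nowhere", 4)], {"S": "E"})

    def test_old_subfamily_mass_at_higher_bins(self):
        """An older activity period shifts landscape mass to higher divergence."""
        tree = read_newick("((X:1.0)Tip:4.0)Root;")
        specs = [
            SubfamilySpec("old", mu=0.5, sigma=0.3, rate=40, element_length=500),
            SubfamilySpec("young", mu=4.5, sigma=0.3, rate=40, element_length=500),
        ]
        cfg = SimConfig(
            host_tree=tree, subfamilies=specs, ancestral_genome_length=30_000,
            subst_rate=0.03, p_tsd=0.0, seed=9,
        )
        sim = simulate_history(cfg)
        genome = sim.genome("X")
        entries = []
        for rec in sim.registry.insertions.values():
            if "X" not in sim.present_taxa(rec.insertion_id):
                continue
            frags = [
                a for a in sim.annotations("X")
                if a.fragment_group == f"ins{rec.insertion_id}"
            ]
            copy = "".join(genome.residues[a.start:a.end] for a in frags)
            if len(copy) != len(rec.element_ids):
                continue
            if rec.strand == "-":
                copy = reverse_complement(copy)
            ref = sim.masters[rec.subfamily][-len(copy):]
            est = k2p_distance(copy, ref, copy_id=f"ins{rec.insertion_id}")
            if not est.saturated:
                entries.append(
                    LandscapeInput(est, rec.subfamily, aligned_bp(copy, ref))
                )
        table = compute_landscape(entries, {"old": "old", "young": "young"})
        bins = np.arange(50)
        mean_bin = {
            g: float((table.row(g) * bins).sum() / table.row(g).sum())
            for g in table.groups
        }
        assert mean_bin["old"] > mean_bin["young"] + 2


class TestExtantActivity:
    def _table(self, bin0):
        bp = np.zeros((1, 50))
        bp[0, 0] = bin0
        bp[0, 10] = 500
        return LandscapeTable(groups=["E"], bp=bp)

    def test_above_threshold_flagged(self):
        assert detect_extant_activity(self._table(150_000)) == {"E": True}

    def test_exact_threshold_not_flagged(self):
        assert detect_extant_activity(self._table(100_000)) == {"E": False}

    def test_old_mass_only_not_flagged(self):
        bp = np.zeros((1, 50))
        bp[0, 5:] = 1e6
        assert detect_extant_activity(LandscapeTable(["E"], bp)) == {"E": False}
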