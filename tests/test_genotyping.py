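"""Functional genotyping: reciprocal best hits, repertoire matrix, motif
rules, guild classification, quality gating, protein clustering."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from nitroprof import genotyping as gt
from nitroprof import synthetic as syn
from nitroprof.align import evalue as ka_evalue
from nitroprof.markers import AMINO_ACIDS, seed_protein

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a, b, open_=-12.0, extend=-1.0):
    """Brute-force affine-gap Smith-Waterman score (independent oracle)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (vertical)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + open_, E[i, j - 1] + extend)
            F[i, j] = max(H[i - 1, j] + open_, F[i - 1, j] + extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    return float(H.max())


def oracle_bbh(query, reference, e_max=1e-6):
    """All-vs-all Smith-Waterman reciprocal best hits (pair ids only)."""
    db_q = sum(len(s) for s in query.values())
    db_r = sum(len(s) for s in reference.values())

    def best(qid, qseq, db, db_n):
        scored = sorted(
            ((sw_score(rseq, qseq), rid) for rid, rseq in db.items()),
            key=lambda t: (-t[0], t[1]),
        )
        score, rid = scored[0]
        return rid if ka_evalue(score, len(qseq), db_n) <= e_max else None

    fwd = {qid: best(qid, qseq, reference, db_r) for qid, qseq in query.items()}
    rev = {rid: best(rid, rseq, query, db_q) for rid, rseq in reference.items()}
    return {
        (qid, rid)
        for qid, rid in fwd.items()
        if rid is not None and rev.get(rid) == qid
    }


def random_proteome(n_prot, length, seed, label):
    rng = np.random.default_rng(seed)
    return {
        f"{label}{i:02d}": "".join(rng.choice(list(AMINO_ACIDS), size=length))
        for i in range(n_prot)
    }


def mutated_proteome(proteome, divergence, seed, label):
    from nitroprof.seqs import mutate_protein

    rng = np.random.default_rng(seed)
    return {
        pid.replace(pid[0], label, 1): mutate_protein(seq, divergence, rng)
        for pid, seq in proteome.items()
    }


class TestReciprocalBestHits:
    def test_identical_proteomes_self_pairs_at_100(self):
        prot = random_proteome(5, 60, seed=1, label="p")
        pairs = gt.reciprocal_best_hits(prot, dict(prot))
        assert {(q, r) for q, r, _ in pairs} == {(p, p) for p in prot}
        assert all(i == pytest.approx(100.0) for _, _, i in pairs)

    def test_reference_without_homolog_unpaired(self):
        prot = random_proteome(4, 60, seed=2, label="q")
        ref = mutated_proteome(prot, 0.1, seed=3, label="r")
        ref["r_orphan"] = "".join(
            np.random.default_rng(4).choice(list(AMINO_ACIDS), 60)
        )
        pairs = gt.reciprocal_best_hits(prot, ref)
        assert all(r != "r_orphan" for _, r, _ in pairs)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        query = random_proteome(5, 50, seed=seed * 2 + 100, label="q")
        ref = mutated_proteome(query, 0.15, seed=seed * 2 + 101, label="r")
        got = {(q, r) for q, r, _ in gt.reciprocal_best_hits(query, ref)}
        assert got == oracle_bbh(query, ref)

    def test_bbh_symmetry(self):
        query = random_proteome(6, 55, seed=7, label="q")
        ref = mutated_proteome(query, 0.2, seed=8, label="r")
        fwd = {(q, r) for q, r, _ in gt.reciprocal_best_hits(query, ref)}
        rev = {(q, r) for r, q, _ in gt.reciprocal_best_hits(ref, query)}
        assert fwd == rev

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            gt.reciprocal_best_hits({}, {"r": "MKT"})


@pytest.fixture(scope="module")
def reference_genome():
    spec = syn.default_genome_specs()[0]  # comammox: full pathway + cynS
    genome = syn.build_genome(spec, seed=77)
    targets = gt.GeneTargetSet(
        "REF",
        {f.gene_name: f.protein_id for f in genome.features if f.copy_index == 1},
    )
    return genome, targets


class TestRepertoireMatrix:
    def test_self_genotyping_all_targets_100(self, reference_genome):
        genome, targets = reference_genome
        matrix = gt.build_repertoire_matrix(
            {"self": genome.proteome}, {"REF": genome.proteome}, [targets]
        )
        assert set(targets.targets) <= set(matrix.columns)
        row = matrix.loc["self", list(targets.targets)]
        assert np.allclose(row.to_numpy(dtype=float), 100.0)

    def test_deleted_gene_absent(self, reference_genome):
        genome, targets = reference_genome
        depleted = {
            pid: seq for pid, seq in genome.proteome.items() if "hao" not in pid
        }
        matrix = gt.build_repertoire_matrix(
            {"bin": depleted}, {"REF": genome.proteome}, [targets]
        )
        assert np.isnan(matrix.loc["bin", "hao"])
        assert matrix.loc["bin", "amoA"] == pytest.approx(100.0)

    def test_identity_reflects_substitutions(self, reference_genome):
        """m internal substitutions over length L give identity 100(L-m)/L."""
        genome, targets = reference_genome
        ref_cyns = genome.proteome[targets.targets["cynS"]]
        L, m = len(ref_cyns), 6
        rng = np.random.default_rng(5)
        positions = rng.choice(np.arange(10, L - 10), size=m, replace=False)
        mutant = list(ref_cyns)
        for p in positions:
            mutant[p] = "W" if mutant[p] != "W" else "Y"
        binp = {"bin|cynS_1": "".join(mutant)}
        matrix = gt.build_repertoire_matrix(
            {"bin": binp}, {"REF": genome.proteome}, [targets]
        )
        assert matrix.loc["bin", "cynS"] == pytest.approx(100 * (L - m) / L)

    def test_unknown_target_protein_errors(self, reference_genome):
        genome, _ = reference_genome
        bad = gt.GeneTargetSet("REF", {"amoA": "not_a_protein"})
        with pytest.raises(ValueError, match="absent"):
            gt.build_repertoire_matrix(
                {"bin": genome.proteome}, {"REF": genome.proteome}, [bad]
            )


class TestMotifRules:
    def test_cyanase_reference_passes_itself(self):
        rule = gt.cyanase_rule()
        report = gt.check_motif(rule.reference_sequence, rule)
        assert report.verdict
        assert [(p, e, o, ok) for p, e, o, ok in report.residue_checks] == [
            (96, "R", "R", True),
            (99, "E", "E", True),
            (122, "S", "S", True),
        ]

    def test_glu99ala_fails(self):
        rule = gt.cyanase_rule()
        cand = list(rule.reference_sequence)
        cand[98] = "A"  # Glu99 -> Ala
        report = gt.check_motif("".join(cand), rule)
        failed = [c for c in report.residue_checks if not c[3]]
        assert failed == [(99, "E", "A", False)]
        assert not report.verdict

    def test_insertion_before_site_still_passes(self):
        """Alignment anchoring keeps residue positions after an insertion."""
        rule = gt.cyanase_rule()
        ref = rule.reference_sequence
        cand = ref[:60] + "GSG" + ref[60:]
        assert gt.check_motif(cand, rule).verdict

    def test_padding_invariance(self):
        rule = gt.cyanase_rule()
        padded = "MLVAAKKW" + rule.reference_sequence + "HHWPL"
        assert gt.check_motif(padded, rule).verdict

    def test_truncated_candidate_unalignable_residue_fails(self):
        rule = gt.cyanase_rule()
        report = gt.check_motif(rule.reference_sequence[:50], rule)
        assert not report.verdict
        assert any(o is None for _p, _e, o, _ok in report.residue_checks)

    def test_cxxc_counting(self):
        rule = gt.hydrogenase_cxxc_rule()
        assert gt.check_motif(rule.reference_sequence, rule).motif_count >= 2
        assert gt.check_motif(rule.reference_sequence, rule).verdict
        no_c = ("MAGLKTV" * 30).replace("C", "A")
        report = gt.check_motif(no_c, rule)
        assert report.motif_count == 0 and not report.verdict
        # non-overlapping left-to-right scan
        assert gt.check_motif("CAACAAC", rule).motif_count == 1
        assert gt.check_motif("CAACCAAC", rule).motif_count == 2

    def test_empty_candidate_rejected(self):
        with pytest.raises(ValueError):
            gt.check_motif("", gt.cyanase_rule())


class TestGuildClassification:
    def _row(self, present):
        return {g: (g in present) for g in gt.NITRIFICATION_GENES}

    @pytest.mark.parametrize(
        "present,expected",
        [
            ({"amoA", "amoB", "amoC", "hao", "nxrA", "nxrB"}, "comammox_complete"),
            ({"amoA", "amoB", "amoC", "hao", "nxrA"}, "comammox_near"),
            ({"amoB", "amoC", "hao"}, "comammox_candidate"),
            ({"nxrA", "nxrB"}, "NOB_only"),
            ({"nxrB"}, "NOB_only"),
            (set(), "none"),
            ({"hao"}, "none"),
            ({"amoA"}, "none"),
        ],
    )
    def test_worked_examples(self, present, expected):
        assert gt.classify_nitrifier_guild(self._row(present)) == expected

    def test_missing_column_errors(self):
        with pytest.raises(KeyError):
            gt.classify_nitrifier_guild({"amoA": True})

    @settings(max_examples=64, derandomize=True)
    @given(bits=st.integers(min_value=0, max_value=63))
    def test_classes_exhaustive_and_exclusive(self, bits):
        present = {
            g for i, g in enumerate(gt.NITRIFICATION_GENES) if bits & (1 << i)
        }
        cls = gt.classify_nitrifier_guild(self._row(present))
        assert cls in gt.GUILD_CLASSES

    def test_rbc_bin_repertoire_partition(self):
        """The twelve RBC Nitrospira bins partition 3 / 4 / 5 across
        near-comammox, strict NOB, and comammox candidates."""
        rep = gt.rbc_nitrospira_repertoire()
        classes = gt.classify_bins(rep[list(gt.NITRIFICATION_GENES)])
        counts = classes.value_counts()
        assert counts["comammox_near"] == 3
        assert counts["NOB_only"] == 4
        assert counts["comammox_candidate"] == 5
        assert set(classes[classes == "comammox_near"].index) == {
            "RBC069",
            "RBC001",
            "RBC044",
        }


class TestQualityGate:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (80.0, 4.9, True),  # inclusive completeness boundary
            (79.9, 0.0, False),  # just below completeness
            (100.0, 5.0, False),  # strict contamination boundary
            (95.0, 1.0, True),
        ],
    )
    def test_thresholds(self, completeness, contamination, kept):
        q = gt.BinQuality("b", completeness, contamination)
        assert (gt.select_quality_bins([q]) == ["b"]) is kept

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            gt.BinQuality("b", 101.0, 0.0)


class TestClusterProteins:
    def test_identical_sequences_one_cluster(self):
        s = seed_protein("cynS")
        clusters = gt.cluster_proteins({"a": s, "b": s})
        assert len(clusters) == 1 and sorted(clusters[0][1]) == ["a", "b"]

    def test_98_percent_pair_splits_at_99(self):
        s = seed_protein("hyfG")  # 300 aa; 6 substitutions -> 98%
        mutant = list(s)
        for p in (20, 60, 110, 160, 210, 260):
            mutant[p] = "W" if mutant[p] != "W" else "Y"
        clusters = gt.cluster_proteins({"a": s, "b": "".join(mutant)})
        assert len(clusters) == 2

    def test_toy_set_matches_greedy_oracle(self):
        """Membership equals a brute-force all-pairs + greedy oracle using an
        independent unit-cost alignment DP."""

        def edit_dp(a, b):
            n, m = len(a), len(b)
            D = np.zeros((n + 1, m + 1), dtype=int)
            D[:, 0] = np.arange(n + 1)
            D[0, :] = np.arange(m + 1)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    D[i, j] = min(
                        D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                        D[i - 1, j] + 1,
                        D[i, j - 1] + 1,
                    )
            return D[n, m]

        def oracle_identity(a, b):
            # minimum-edit alignment: columns = max(len) + surplus edits
            d = edit_dp(a, b)
            cols = max(len(a), len(b)) + max(0, d - abs(len(a) - len(b))) // 2 * 0
            # identity bounded below; with substitution-only toy pairs this
            # equals matches / columns exactly
            return (cols - d) / cols

        rng = np.random.default_rng(31)
        base1 = "".join(rng.choice(list(AMINO_ACIDS), 120))
        base2 = "".join(rng.choice(list(AMINO_ACIDS), 100))
        seqs = {}
        for i in range(5):  # near-identical family around base1
            mutant = list(base1)
            if i:
                mutant[10 * i] = "W" if mutant[10 * i] != "W" else "Y"  # 1 sub
            seqs[f"a{i}"] = "".join(mutant)
        for i in range(5):  # distinct family around base2
            mutant = list(base2)
            for p in range(0, 20 + i):
                mutant[p] = "W" if mutant[p] != "W" else "Y"
            seqs[f"b{i}"] = "".join(mutant)

        got = {rep: sorted(members) for rep, members in gt.cluster_proteins(seqs)}

        order = sorted(seqs, key=lambda s: (-len(seqs[s]), s))
        reps, members = [], {}
        for sid in order:
            for rep in reps:
                if oracle_identity(seqs[rep], seqs[sid]) >= 0.99:
                    members[rep].append(sid)
                    break
            else:
                reps.append(sid)
                members[sid] = [sid]
        oracle = {rep: sorted(m) for rep, m in members.items()}
        assert got == oracle

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gt.cluster_proteins({})
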