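import math
import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corecruit import resources
from corecruit.motif_scan import (
    ContactSpec,
    MotifError,
    MotifHit,
    build_pssm,
    check_contacts,
    compile_pattern,
    scan_pssm,
    scan_strict,
)
from corecruit.seqio import AMINO_ACIDS, ProteinRecord


class TestCompilePattern:
    def test_ctbp_class_pattern(self):
        p = compile_pattern("P[ILMV]D[ILMV]S")
        assert p.width == 5
        assert p.columns[1] == frozenset("ILMV")
        assert p.columns[0] == frozenset("P")

    def test_literal_pattern(self):
        p = compile_pattern("WRPW")
        assert p.width == 4
        assert all(len(c) == 1 for c in p.columns)

    def test_full_wildcard(self):
        p = compile_pattern("[ACDEFGHIKLMNPQRSTVWY]")
        assert p.width == 1
        assert p.columns[0] == frozenset(AMINO_ACIDS)

    def test_empty_brackets_rejected(self):
        with pytest.raises(MotifError):
            compile_pattern("P[]S")

    def test_non_residue_rejected(self):
        with pytest.raises(MotifError):
            compile_pattern("PXD")


class TestScanStrict:
    def test_strict_instance_found(self):
        protein = ProteinRecord(id="p", sequence="FADNHPVDLSNSHRG")
        hits = scan_strict(compile_pattern("P[ILMV]D[ILMV]S"), protein)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].matched) == (6, "PVDLS")
        assert math.isinf(hits[0].score)

    def test_near_canonical_instance_missed(self):
        # terminal T violates the S column: motivates the PSSM mode
        protein = ProteinRecord(id="p", sequence="LHYDNPLDLTNRLDE")
        assert scan_strict(compile_pattern("P[ILMV]D[ILMV]S"), protein) == []

    def test_sequence_shorter_than_pattern(self):
        protein = ProteinRecord(id="p", sequence="PVD")
        assert scan_strict(compile_pattern("P[ILMV]D[ILMV]S"), protein) == []

    def test_overlapping_hits_all_reported(self):
        protein = ProteinRecord(id="p", sequence="AAAA")
        hits = scan_strict(compile_pattern("AA"), protein)
        assert [h.start for h in hits] == [1, 2, 3]

    def test_agrees_with_regex_oracle_on_random_inputs(self):
        rng = random.Random(13)
        for _ in range(1000):
            seq = "".join(rng.choices(AMINO_ACIDS, k=rng.randint(1, 40)))
            width = rng.randint(1, 4)
            cols = [
                "".join(sorted(rng.sample(AMINO_ACIDS, rng.randint(1, 5))))
                for _ in range(width)
            ]
            spec = "".join(f"[{c}]" for c in cols)
            protein = ProteinRecord(id="p", sequence=seq)
            got = [(h.start, h.matched) for h in scan_strict(compile_pattern(spec), protein)]
            regex = "(?=(" + "".join(f"[{c}]" for c in cols) + "))"
            expected = [
                (m.start() + 1, seq[m.start(): m.start() + width])
                for m in re.finditer(regex, seq)
            ]
            assert got == expected

    def test_region_flagging(self):
        protein = ProteinRecord(
            id="p", sequence="PVDLSAAAPVDLS", region_boundary=6
        )
        hits = scan_strict(compile_pattern("P[ILMV]D[ILMV]S"), protein)
        assert [(h.start, h.in_region) for h in hits] == [(1, True), (9, False)]


class TestBuildPssm:
    def test_degenerate_training_set_consensus_is_max(self):
        pssm = build_pssm(["PVDLS", "PVDLS", "PVDLS"])
        assert pssm.consensus == "PVDLS"
        assert pssm.score_window("PVDLS") == pytest.approx(pssm.max_score)

    def test_table_instances_all_above_threshold(self):
        instances = resources.ctbp_instances()
        pssm = build_pssm(instances)
        # independent recomputation of the scoring formula as oracle
        def oracle_score(window):
            total = 0.0
            for c, aa in enumerate(window):
                count = sum(1 for s in instances if s[c] == aa)
                total += math.log2((count + 0.5 / 20) / (len(instances) + 0.5))
                total -= math.log2(1 / 20)
            return total

        for inst in set(instances):
            assert pssm.score_window(inst) == pytest.approx(oracle_score(inst))
            assert pssm.score_window(inst) >= pssm.threshold
        assert pssm.score_window("PLDLT") >= pssm.threshold

    def test_two_instance_symmetry(self):
        pssm = build_pssm(["AA", "CC"])
        for col in pssm.scores:
            assert col["A"] == pytest.approx(col["C"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(MotifError):
            build_pssm(["AA", "AAA"])

    def test_zero_background_rejected(self):
        bg = {aa: (0.0 if aa == "W" else 1 / 19) for aa in AMINO_ACIDS}
        with pytest.raises(MotifError):
            build_pssm(["WW", "WA"], background=bg)

    def test_leave_one_out_threshold_not_higher(self):
        instances = resources.ctbp_instances()
        default = build_pssm(instances)
        loo = build_pssm(instances, leave_one_out=True)
        assert loo.threshold <= default.threshold


class TestScanPssm:
    def test_gro_core_recovered(self):
        pssm = resources.gro_core_pssm()
        protein = ProteinRecord(id="p", sequence="SHMIAGSLTPPDKVNGEHGHQL")
        hits = scan_pssm(pssm, protein)
        assert any(h.matched == "GSLTPPDKV" and h.start == 6 for h in hits)

    def test_divergent_gro_instance_recovered(self):
        pssm = resources.gro_core_pssm()
        protein = ProteinRecord(id="p", sequence="MQLISGSMTSHDKVNGDQHSLG")
        hits = scan_pssm(pssm, protein)
        assert any(h.matched == "GSMTSHDKV" for h in hits)

    def test_shuffled_sequences_rarely_hit(self):
        # empirical false-positive oracle over 1,000 residue shuffles
        pssm = resources.gro_core_pssm()
        seq = list("SHMIAGSLTPPDKVNGEHGHQL")
        rng = random.Random(23)
        n_hits = 0
        for _ in range(1000):
            rng.shuffle(seq)
            protein = ProteinRecord(id="s", sequence="".join(seq))
            n_hits += len(scan_pssm(pssm, protein))
        assert n_hits <= 10  # ~23-bit threshold: chance hits essentially absent

    def test_training_instances_recovered_in_isolation(self):
        rng = random.Random(5)
        for _ in range(25):
            width = rng.randint(3, 8)
            instances = [
                "".join(rng.choices(AMINO_ACIDS, k=width)) for _ in range(rng.randint(2, 6))
            ]
            pssm = build_pssm(instances)
            for inst in instances:
                hits = scan_pssm(pssm, ProteinRecord(id="i", sequence=inst))
                assert any(h.start == 1 and h.matched == inst for h in hits)

    def test_threshold_monotonicity(self):
        pssm = resources.ctbp_relaxed_pssm()
        rng = random.Random(3)
        seq = "".join(rng.choices(AMINO_ACIDS, k=400))
        protein = ProteinRecord(id="p", sequence=seq)
        counts = [
            len(scan_pssm(pssm, protein, threshold_override=t))
            for t in (-10.0, 0.0, 5.0, pssm.threshold, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_flank_concatenation_shifts_hits(self):
        pssm = resources.ctbp_relaxed_pssm()
        protein = ProteinRecord(id="p", sequence="FADNHPVDLSNSHRG")
        base = scan_pssm(pssm, protein)
        flank = "GGGGGGGG"
        shifted = scan_pssm(
            pssm, ProteinRecord(id="p", sequence=flank + protein.sequence + flank)
        )
        assert [(h.start - len(flank), h.matched) for h in shifted] == [
            (h.start, h.matched) for h in base
        ]

    @settings(max_examples=50, deadline=None)
    @given(
        seq=st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=60),
        delta=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_raising_threshold_never_adds_hits(self, seq, delta):
        pssm = resources.gro_core_pssm()
        protein = ProteinRecord(id="h", sequence=seq)
        low = scan_pssm(pssm, protein, threshold_override=pssm.threshold - delta)
        high = scan_pssm(pssm, protein, threshold_override=pssm.threshold + delta)
        assert len(high) <= len(low)
        assert {(h.start, h.matched) for h in high} <= {
            (h.start, h.matched) for h in low
        }


class TestCheckContacts:
    wt_region = "GGRLQFFKDGKFILELARSKDGDKSGWVSVTRKTFRPPS"
    mut_region = "GGRAQAFKDGKFIAEAARSKDGDKSGAVSVTRKTFRPPS"

    def _hit(self, seq):
        return (
            ProteinRecord(id="p", sequence=seq),
            MotifHit(
                protein_id="p",
                pattern_name="SBD",
                start=2,
                end=16,
                matched=seq[1:16],
                score=0.0,
            ),
        )

    def test_wild_type_all_satisfied(self):
        protein, hit = self._hit(self.wt_region)
        report = check_contacts(hit, protein, resources.SBD_CONTACTS)
        assert report.all_satisfied
        assert len(report.satisfied) == 4
        assert protein.sequence[report.w_position - 1] == "W"
        assert report.w_follower == "V"

    def test_mutant_all_violated_no_w(self):
        protein, hit = self._hit(self.mut_region)
        report = check_contacts(hit, protein, resources.SBD_CONTACTS)
        assert len(report.violated) == 4
        assert report.w_position is None

    def test_empty_spec_vacuous(self):
        protein, hit = self._hit(self.wt_region)
        report = check_contacts(hit, protein, ContactSpec(name="none"))
        assert report.all_satisfied
        assert report.satisfied == ()

    def test_offset_beyond_protein_rejected(self):
        protein = ProteinRecord(id="p", sequence="GRL")
        hit = MotifHit("p", "x", 1, 3, "GRL", 0.0)
        spec = ContactSpec(name="far", contacts=((5, frozenset("L")),))
        with pytest.raises(MotifError):
            check_contacts(hit, protein, spec)
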