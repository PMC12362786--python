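"""Consequence classification, label harmonization, consensus and frequency rules."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deafscape.catalog import (ConflictClass, ConsequenceClass, FrequencyBin,
                               ReclassConfig, ReclassDecision, VariantRecord,
                               apply_frequency_reclassification,
                               classify_consequence, consensus_and_conflict,
                               frequency_bin, normalize_source_label,
                               summarize_catalog)
from deafscape.exceptions import (InvalidInputError, MissingDataError,
                                  OutOfScopeError, UnknownDialectError)

from conftest import build_transcript


def _variant(t, pos0, ref, alt, **kw):
    return VariantRecord(gene=t.gene, transcript_id=t.transcript_id,
                         chrom=t.chrom, pos=pos0 + 1, ref=ref, alt=alt, **kw)


class TestClassifyConsequence:
    def test_splice_offsets(self, three_exon_transcript):
        t = three_exon_transcript
        donor = t.coding_segments()[0][1]  # first intronic base after exon 1
        assert classify_consequence(_variant(t, donor + 1, "A", "C"), t) \
            is ConsequenceClass.CANONICAL_SPLICE           # +2
        acceptor = t.coding_segments()[1][0]
        assert classify_consequence(_variant(t, acceptor - 5, "A", "C"), t) \
            is ConsequenceClass.SPLICE_REGION              # -5
        assert classify_consequence(_variant(t, donor + 20, "A", "C"), t) \
            is ConsequenceClass.DEEP_INTRONIC

    def test_codon_level_classes(self, three_exon_transcript):
        t = three_exon_transcript
        # cds 6 is the third base of codon 2 (GCT, Ala): T>C keeps Ala
        g = t.cds_to_genomic(6)
        assert classify_consequence(_variant(t, g, "T", "C"), t) \
            is ConsequenceClass.SYNONYMOUS
        # T>A gives GCA, still Ala; T>G gives GCG; second base C>T -> GTT Val
        g2 = t.cds_to_genomic(5)
        assert classify_consequence(_variant(t, g2, "C", "T"), t) \
            is ConsequenceClass.MISSENSE
        # start codon disruption
        g_start = t.cds_to_genomic(1)
        assert classify_consequence(_variant(t, g_start, "A", "C"), t) \
            is ConsequenceClass.START_LOSS
        # codon 5 of the filler sequence is AAG (Lys); A>T at cds 13 -> TAG stop
        assert t.cds_sequence[12:15] == "AAG"
        g_stop = t.cds_to_genomic(13)
        assert classify_consequence(_variant(t, g_stop, "A", "T"), t) \
            is ConsequenceClass.STOP_GAIN

    def test_indels_and_noncoding(self, three_exon_transcript):
        t = three_exon_transcript
        g = t.cds_to_genomic(30)
        ref2 = t.cds_sequence[29:31]
        assert classify_consequence(_variant(t, g, ref2, ref2[0]), t) \
            is ConsequenceClass.FRAMESHIFT
        ref4 = t.cds_sequence[29:33]
        assert classify_consequence(_variant(t, g, ref4, ref4[0]), t) \
            is ConsequenceClass.INFRAME_INDEL
        assert classify_consequence(_variant(t, t.cds_start - 5, "A", "C"), t) \
            is ConsequenceClass.UTR5
        assert classify_consequence(_variant(t, t.cds_end + 5, "A", "C"), t) \
            is ConsequenceClass.UTR3
        assert classify_consequence(_variant(t, t.tx_start - 100, "A", "C"), t) \
            is ConsequenceClass.UPSTREAM_DOWNSTREAM
        with pytest.raises(OutOfScopeError):
            classify_consequence(_variant(t, t.tx_end + 5000, "A", "C"), t)

    def test_minus_strand_codon_resolution(self):
        t = build_transcript([300, 150, 90], strand="-")
        g = t.cds_to_genomic(6)   # third base of codon 2 (T on coding strand)
        # forward-strand alleles are complements of the coding-strand change
        assert classify_consequence(_variant(t, g, "A", "G"), t) \
            is ConsequenceClass.SYNONYMOUS


class TestLabels:
    @pytest.mark.parametrize("source,raw,expected", [
        ("HGMD", "DM", "P"),
        ("HGMD", "DM?", "LP"),
        ("ClinVar", "Likely benign", "LB"),
        ("ClinVar", "Pathogenic", "P"),
        ("DVD", "", "unclassified"),
        ("CDGC", "Uncertain significance", "VUS"),
        ("DVD", "weird string", "unclassified"),
    ])
    def test_normalization(self, source, raw, expected):
        assert normalize_source_label(source, raw) == expected

    def test_unknown_source(self):
        with pytest.raises(UnknownDialectError):
            normalize_source_label("NotASource", "Pathogenic")

    def test_consensus_concordant(self):
        res = consensus_and_conflict({"CDGC": "Pathogenic",
                                      "ClinVar": "Likely pathogenic"})
        assert res.consensus == "P/LP"
        assert res.agreement_count == 2
        assert res.conflict_class is ConflictClass.NONE

    def test_conflict_classes(self):
        assert consensus_and_conflict(
            {"CDGC": "Pathogenic", "ClinVar": "Benign"}
        ).conflict_class is ConflictClass.PLP_VS_BLB
        res = consensus_and_conflict(
            {"CDGC": "Likely pathogenic", "DVD": "Uncertain significance"})
        assert res.conflict_class is ConflictClass.PLP_VS_VUS
        assert res.consensus == "P/LP"

    def test_empty_labels_error(self):
        with pytest.raises(MissingDataError):
            consensus_and_conflict({})

    @given(st.dictionaries(
        st.sampled_from(["CDGC", "ClinVar", "DVD"]),
        st.sampled_from(["Pathogenic", "Likely pathogenic", "Benign",
                         "Likely benign", "Uncertain significance", "junk"]),
        min_size=1, max_size=3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_consensus_matches_pairwise_brute_force(self, labels):
        """Conflict flags agree with an exhaustive pairwise stratum check."""
        res = consensus_and_conflict(labels)
        norm = {s: normalize_source_label(s, l) for s, l in labels.items()}
        strata = {"P": "plp", "LP": "plp", "B": "blb", "LB": "blb",
                  "VUS": "vus", "unclassified": "un"}
        pairs = [(strata[a], strata[b])
                 for a, b in itertools.combinations(norm.values(), 2)]
        blb_conflict = any({x, y} == {"plp", "blb"} for x, y in pairs)
        vus_conflict = any({x, y} == {"plp", "vus"} for x, y in pairs)
        if blb_conflict:
            assert res.conflict_class is ConflictClass.PLP_VS_BLB
        elif vus_conflict:
            assert res.conflict_class is ConflictClass.PLP_VS_VUS
        else:
            assert res.conflict_class is ConflictClass.NONE

    @given(st.permutations(["CDGC", "ClinVar", "DVD", "HGMD"]))
    @settings(max_examples=24, deadline=None, derandomize=True)
    def test_consensus_source_order_invariant(self, order):
        raw = {"CDGC": "Pathogenic", "ClinVar": "Uncertain significance",
               "DVD": "Likely benign", "HGMD": "DM"}
        reference = consensus_and_conflict(raw)
        shuffled = consensus_and_conflict({s: raw[s] for s in order})
        assert shuffled.consensus == reference.consensus
        assert shuffled.conflict_class == reference.conflict_class
        assert shuffled.agreement_count == reference.agreement_count


class TestFrequencyRules:
    @pytest.mark.parametrize("ac,maf,expected", [
        (0, 0.0, FrequencyBin.ABSENT),
        (1, 1e-6, FrequencyBin.SINGLETON),
        (2, 1e-6, FrequencyBin.DOUBLETON),
        (3, 1e-6, FrequencyBin.TRIPLETON),
        (4, 1e-6, FrequencyBin.QUADRUPLETON),
        (10, 0.0001, FrequencyBin.RARE_POLYMORPHIC),
        (10, 0.001, FrequencyBin.COMMON),
        (500, 0.01, FrequencyBin.COMMON),
    ])
    def test_bins(self, ac, maf, expected):
        assert frequency_bin(ac, maf) is expected

    def test_negative_ac_rejected(self):
        with pytest.raises(InvalidInputError):
            frequency_bin(-1, 0.0)

    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0, max_value=0.5, allow_nan=False))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_binning_is_a_partition(self, ac, maf):
        """Every (AC, MAF) lands in exactly one bin, consistent with its rules."""
        b = frequency_bin(ac, maf)
        if ac == 0:
            assert b is FrequencyBin.ABSENT
        elif ac <= 4:
            assert b.value in ("singleton", "doubleton", "tripleton",
                              "quadrupleton")
        elif maf < 0.0002:
            assert b is FrequencyBin.RARE_POLYMORPHIC
        else:
            assert b is FrequencyBin.COMMON

    def _var(self, inheritance, maf):
        return VariantRecord(gene="G", transcript_id="T", chrom="c", pos=1,
                             ref="A", alt="C", inheritance=inheritance,
                             allele_frequency={"gnomad": maf})

    @pytest.mark.parametrize("inh,maf,expected", [
        ("AR", 0.006, ReclassDecision.TO_BLB_FREQUENCY),
        ("AD", 0.002, ReclassDecision.TO_BLB_FREQUENCY),
        ("AR", 1e-5, ReclassDecision.UNCHANGED),
        ("AD/AR", 0.002, ReclassDecision.UNCHANGED),   # recessive threshold
        ("AD/AR", 0.006, ReclassDecision.TO_BLB_FREQUENCY),
    ])
    def test_primary_frequency_rule(self, inh, maf, expected):
        assert apply_frequency_reclassification(self._var(inh, maf)).decision \
            is expected

    def test_secondary_and_control_rules(self):
        v = self._var("AR", 0.003)  # above half of 0.5%, below 0.5%
        assert apply_frequency_reclassification(v, benign_prediction=True) \
            .decision is ReclassDecision.TO_BLB_FREQUENCY_PLUS_PREDICTION
        assert apply_frequency_reclassification(v).decision \
            is ReclassDecision.UNCHANGED
        ad = self._var("AD", 1e-5)
        assert apply_frequency_reclassification(ad, control_count=2).decision \
            is ReclassDecision.TO_BLB_IN_CONTROLS
        assert apply_frequency_reclassification(ad, control_count=1).decision \
            is ReclassDecision.UNCHANGED
        # AR variants never trigger the control rule
        ar = self._var("AR", 1e-5)
        assert apply_frequency_reclassification(ar, control_count=5).decision \
            is ReclassDecision.UNCHANGED

    def test_missing_inheritance_not_applicable(self):
        v = self._var(None, 0.01)
        assert apply_frequency_reclassification(v).decision \
            is ReclassDecision.NOT_APPLICABLE

    def test_reclassification_idempotent(self):
        cfg = ReclassConfig(min_controls=3)
        v = self._var("AD", 0.002)
        first = apply_frequency_reclassification(v, config=cfg)
        second = apply_frequency_reclassification(v, config=cfg)
        assert first == second


class TestSummary:
    def test_empty_catalog(self):
        df = summarize_catalog([])
        assert df.empty

    def test_pure_missense_catalog(self):
        recs = [VariantRecord(gene="G", transcript_id="T", chrom="c", pos=i,
                              ref="A", alt="C",
                              consequence=ConsequenceClass.MISSENSE,
                              allele_count={"gnomad": 1},
                              allele_frequency={"gnomad": 1e-6})
                for i in range(1, 11)]
        df = summarize_catalog(recs)
        csq = df[df.stratification == "consequence"]
        assert list(csq.category) == ["missense"]
        assert csq.proportion.iloc[0] == 1.0
        for _, grp in df.groupby("stratification"):
            assert grp.proportion.sum() == pytest.approx(1.0)
            assert grp["count"].sum() == 10
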