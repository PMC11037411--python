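"""Modification-gated digestion: site calls, cuts, fragments."""

import random

import pytest

from mdrekit import (
    DistanceRange,
    EnzymeModel,
    MethylomeTrack,
    Nicking,
    ReaderContext,
    SeqRecord,
    WithinSite,
    apply_mtase,
    call_sites,
    fragment_lengths,
    load_mtase_pool,
    predict_cuts,
    two_site_efficiency,
)
from mdrekit.digestion import labeled_fragment_length
from mdrekit.motif_algebra import parse_pattern


def _duplex(duplexes, state):
    for label, seq, track in duplexes:
        if label == state:
            return seq, track
    raise KeyError(state)


class TestCallSites:
    def test_dpni_full_duplex(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M+/M+")
        calls = call_sites(seq, track, enzymes["DpnI"])
        assert len(calls) == 1
        assert calls[0].methylation_state == "full"
        assert calls[0].activity == "high"

    def test_mboi_hemi_resistant(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M+/M-")
        (call,) = call_sites(seq, track, enzymes["MboI"])
        assert call.methylation_state == "hemi_top"
        assert call.activity == "none"

    def test_sau3ai_indifferent(self, duplexes, enzymes):
        for state in ("M+/M+", "M-/M-"):
            seq, track = _duplex(duplexes, state)
            (call,) = call_sites(seq, track, enzymes["Sau3AI"])
            assert call.activity == "high"

    def test_hemi_orientations_distinguished(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M-/M+")
        (call,) = call_sites(seq, track, enzymes["DpnI"])
        assert call.methylation_state == "hemi_bottom"

    def test_track_ownership_checked(self, duplexes, enzymes):
        seq, _ = _duplex(duplexes, "M+/M+")
        with pytest.raises(ValueError):
            call_sites(seq, MethylomeTrack("other"), enzymes["DpnI"])

    def test_revcomp_invariance(self, enzymes):
        # reverse-complementing sequence and track together maps site
        # calls to mirrored coordinates with hemi states swapped
        dam = load_mtase_pool()["Dam"]
        seq = SeqRecord("s", "CCGATCGGAAGGGGATCCCAA")
        full = apply_mtase(seq, dam)
        hemi = MethylomeTrack("s", {m for m in full.marks if m[1] == "top"})
        n = len(seq)
        L = 4
        rc_seq = seq.revcomp()
        rc_track = MethylomeTrack(
            "s",
            {(n - 1 - p, "bottom" if s == "top" else "top", m) for p, s, m in hemi.marks},
        )
        fwd = call_sites(seq, hemi, enzymes["DpnI"])
        rev = call_sites(rc_seq, rc_track, enzymes["DpnI"])
        swap = {"hemi_top": "hemi_bottom", "hemi_bottom": "hemi_top",
                "full": "full", "none": "none"}
        fwd_mapped = sorted((n - L - c.site_start, swap[c.methylation_state]) for c in fwd)
        assert fwd_mapped == sorted((c.site_start, c.methylation_state) for c in rev)


class TestPredictCuts:
    def test_dpni_blunt_cut_printed_duplex(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M+/M+")
        res = predict_cuts(seq, track, enzymes["DpnI"])
        assert res.ds_cuts == [(19, 19)]  # blunt, after 1-based position 20
        assert fragment_lengths(res, seq) == [20, 40]
        assert labeled_fragment_length(res, seq) == 20

    def test_mboi_overhang_cut_unmodified_duplex(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M-/M-")
        res = predict_cuts(seq, track, enzymes["MboI"])
        assert res.ds_cuts == [(17, 21)]  # 4-nt 5' overhang
        assert labeled_fragment_length(res, seq) == 18

    def test_inactive_sites_contribute_nothing(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M-/M-")
        res = predict_cuts(seq, track, enzymes["DpnI"])
        assert res.ds_cuts == []
        assert labeled_fragment_length(res, seq) is None

    def test_distance_range_interval(self, enzymes):
        dam = load_mtase_pool()["Dam"]
        seq = SeqRecord("s", "C" * 30 + "GATC" + "C" * 30)
        track = apply_mtase(seq, dam)
        res = predict_cuts(seq, track, enzymes["Ahi29725I"])
        # site [30,34); N1-23 on both flanks
        assert (34 + 1, 34 + 23) in res.intervals
        assert (30 - 1 - 23, 30 - 1 - 1) in res.intervals
        for lo, hi in res.intervals:  # never inside the reader span
            assert hi < 30 or lo > 32

    def test_htuiii_paired_site_nick(self, enzymes):
        dam = load_mtase_pool()["Dam"]
        seq = SeqRecord("s", "G" * 10 + "GATC" + "C" * 14 + "GATC" + "G" * 10)
        track = apply_mtase(seq, dam)
        res = predict_cuts(seq, track, enzymes["HtuIII"])
        # top-strand nick one N upstream of the first site only
        assert res.nicks == [("top", 8)]

    def test_htuiii_isolated_site_no_nick(self, enzymes):
        dam = load_mtase_pool()["Dam"]
        seq = SeqRecord("s", "G" * 10 + "GATC" + "G" * 10)
        track = apply_mtase(seq, dam)
        assert predict_cuts(seq, track, enzymes["HtuIII"]).nicks == []

    def test_partial_activity_flags_partial(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M+/M-")
        res = predict_cuts(seq, track, enzymes["FcyTI"])
        assert res.completeness == "partial"
        assert res.ds_cuts == [(19, 19)]


class TestTwoSite:
    @pytest.mark.parametrize(
        "spacer,expected",
        [
            (13, "fast"), (20, "fast"), (27, "fast"),
            (8, "slow"), (9, "slow"), (11, "slow"),
            (43, "slow"), (50, "slow"), (1000, "slow"),
            (7, "unspecified"), (12, "unspecified"),
            (28, "unspecified"), (42, "unspecified"),
        ],
    )
    def test_hhiv4i_spacer_classes(self, enzymes, spacer, expected):
        assert two_site_efficiency(spacer, enzymes["HhiV4I"]) == expected

    def test_rule_absent_error(self, enzymes):
        with pytest.raises(ValueError, match="two-site"):
            two_site_efficiency(20, enzymes["DpnI"])

    def test_negative_spacer_rejected(self, enzymes):
        with pytest.raises(ValueError):
            two_site_efficiency(-1, enzymes["HhiV4I"])


class TestFragments:
    def test_linear_single_cut(self, duplexes, enzymes):
        seq, track = _duplex(duplexes, "M+/M+")
        res = predict_cuts(seq, track, enzymes["DpnI"])
        assert sum(fragment_lengths(res, seq)) == len(seq)

    def test_circular_counts(self, enzymes):
        dam = load_mtase_pool()["Dam"]
        from mdrekit import gen_plasmid

        plasmid = gen_plasmid([30], seed=5)
        track = apply_mtase(plasmid, dam)
        res = predict_cuts(plasmid, track, enzymes["DpnI"])
        frags = fragment_lengths(res, plasmid)
        assert len(frags) == 2  # n cuts -> n fragments on a circle
        assert sum(frags) == len(plasmid)

    def test_circular_uncut(self, enzymes):
        plasmid = SeqRecord("p", "GGCC" * 20, topology="circular")
        res = predict_cuts(plasmid, MethylomeTrack("p"), enzymes["DpnI"])
        assert fragment_lengths(res, plasmid) == [len(plasmid)]

    def test_distance_range_needs_midpoint_resolution(self, enzymes):
        dam = load_mtase_pool()["Dam"]
        seq = SeqRecord("s", "C" * 30 + "GATC" + "C" * 30)
        track = apply_mtase(seq, dam)
        res = predict_cuts(seq, track, enzymes["Ahi29725I"])
        with pytest.raises(ValueError):
            fragment_lengths(res, seq)
        frags = fragment_lengths(res, seq, resolve="midpoint")
        assert sum(frags) == len(seq)

    def test_conservation_random_substrates(self, enzymes):
        """Fragment lengths sum to substrate length for random substrates,
        topologies and cut geometries; zero-mark tracks give zero cuts for
        methylation-requiring enzymes."""
        rng = random.Random(42)
        dam = load_mtase_pool()["Dam"]
        reader = ReaderContext.dam_gatc()
        for i in range(300):
            n = rng.randint(40, 200)
            bases = "".join(rng.choices("ACGT", k=n))
            topo = rng.choice(["linear", "circular"])
            seq = SeqRecord(f"r{i}", bases, topo)
            enz = EnzymeModel(
                name="rand",
                reader=reader,
                mode=WithinSite(rng.randint(-1, 3), rng.randint(-1, 3)),
                response={
                    "full": "high",
                    "hemi_top": rng.choice(["high", "partial", "none"]),
                    "hemi_bottom": rng.choice(["high", "partial", "none"]),
                    "none": "none",
                },
            )
            track = apply_mtase(seq, dam)
            res = predict_cuts(seq, track, enz)
            assert sum(fragment_lengths(res, seq)) == n
            empty = MethylomeTrack(seq.id)
            assert predict_cuts(seq, empty, enz).ds_cuts == []

    def test_mboi_dpni_site_equivalence(self, enzymes):
        # same sites, opposite gates: MboI cut count on naked DNA equals
        # DpnI cut count on the Dam-saturated track
        rng = random.Random(7)
        dam = load_mtase_pool()["Dam"]
        for i in range(20):
            seq = SeqRecord(f"s{i}", "".join(rng.choices("ACGT", k=150)))
            naked = MethylomeTrack(seq.id)
            full = apply_mtase(seq, dam)
            mboi = predict_cuts(seq, naked, enzymes["MboI"])
            dpni = predict_cuts(seq, full, enzymes["DpnI"])
            assert len(mboi.ds_cuts) == len(dpni.ds_cuts)


class TestResponseMatrix:
    def test_fig4_matrix(self, duplexes, enzymes):
        from mdrekit import oligo_response_matrix

        names = ["DpnI", "MboI", "FcyTI", "HhiV4I", "Ahi29725I", "Apa233I"]
        tab = oligo_response_matrix(duplexes, [enzymes[n] for n in names])
        assert tab.loc["DpnI"].tolist() == ["high", "partial", "partial", "none"]
        assert tab.loc["FcyTI"].tolist() == ["high", "partial", "partial", "none"]
        assert tab.loc["MboI"].tolist() == ["none", "none", "none", "high"]
        assert tab.loc["HhiV4I"].tolist() == ["high", "partial", "partial", "partial"]
        assert tab.loc["Ahi29725I"].tolist() == ["high", "partial", "partial", "none"]
        assert tab.loc["Apa233I"].tolist() == ["high", "high", "high", "none"]


class TestEnzymeModelValidation:
    def test_response_map_total(self):
        with pytest.raises(ValueError, match="missing states"):
            EnzymeModel(
                name="x",
                reader=ReaderContext.dam_gatc(),
                mode=WithinSite(1, 1),
                response={"full": "high"},
            )

    def test_distance_range_validation(self):
        with pytest.raises(ValueError):
            DistanceRange(5, 2)

    def test_degenerate_reader_supported(self):
        # relaxed Sm6ATS reader finds GATC sites too
        dam = load_mtase_pool()["Dam"]
        seq = SeqRecord("s", "CCGATCCC")
        track = apply_mtase(seq, dam)
        enz = EnzymeModel(
            name="relaxed",
            reader=ReaderContext(pattern=parse_pattern("SATS"), methyl_index=1),
            mode=WithinSite(1, 1),
            response={"full": "high", "hemi_top": "partial",
                      "hemi_bottom": "partial", "none": "none"},
        )
        calls = call_sites(seq, track, enz)
        assert any(c.methylation_state == "full" for c in calls)
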