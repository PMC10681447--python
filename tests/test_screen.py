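"""The four-criterion decision rule and the inhibitory-region search."""

import dataclasses

import numpy as np
import pytest

from amphiscreen.helicity import BuiltinHelicity, ExternalScores
from amphiscreen.peptide_io import PeptideRecord
from amphiscreen.physchem import charge_profile, mean_windowed_moment
from amphiscreen.screen import (
    Region,
    ScreenConfig,
    evaluate,
    find_region,
    screen_batch,
    screen_record,
)

from conftest import BMAP28, NPY_FULL, NPY_REGION, random_peptide


def brute_force_region(record, config, source):
    """Exhaustive substring oracle: longest passing substring, ties N-terminal."""
    best = None
    total = len(record.sequence)
    for start0 in range(total):
        for length in range(config.len_min, min(total - start0, config.len_max) + 1):
            sub = record.sequence[start0 : start0 + length]
            cand = PeptideRecord(
                record.id, sub,
                n_term_protected=record.n_term_protected and start0 == 0,
                c_term_protected=record.c_term_protected
                and start0 + length == total,
            )
            helicity = source.score(
                sub, record_id=None,
                n_term_protected=cand.n_term_protected,
                c_term_protected=cand.c_term_protected,
            )
            uh = mean_windowed_moment(sub, window=config.window)
            prof = charge_profile(cand)
            basics = sum(1 for q in prof.per_residue if q > 0.5)
            ok = (
                helicity >= config.helicity_min
                and uh >= config.uh_min
                and basics >= length / config.positive_per_residues
                and config.len_min <= length <= config.len_max
            )
            # outer loop ascends start, so the first hit at a given length is
            # the most N-terminal; replace only when strictly longer
            if ok and (best is None or length > best[1]):
                best = (start0, length)
    return None if best is None else (best[0] + 1, best[0] + best[1])


class TestEvaluate:
    def test_bmap28_with_published_score_passes_all(self):
        ext = ExternalScores({"BMAP28": 1.6})
        props = evaluate(PeptideRecord("BMAP28", BMAP28), ScreenConfig(), ext)
        assert props.all_pass
        assert props.pass_helicity and props.pass_uh and props.pass_ncpr and props.pass_length

    def test_seventeen_residues_fail_length_regardless(self):
        ext = ExternalScores({"x": 99.0})
        props = evaluate(PeptideRecord("x", "KLALKLALKALKAALKL"[:17]), ScreenConfig(), ext)
        assert props.length == 17 and not props.pass_length
        assert not props.all_pass

    def test_polyglycine_fails_amphipathicity_and_cationicity(self):
        props = evaluate(PeptideRecord("g", "G" * 20))
        assert not props.pass_uh and not props.pass_ncpr
        assert props.uh == pytest.approx(0.0, abs=0.05)
        assert props.basic_count == 0

    def test_flags_match_thresholds(self):
        rng = np.random.default_rng(21)
        cfg = ScreenConfig()
        for _ in range(25):
            seq = random_peptide(rng, int(rng.integers(10, 60)))
            p = evaluate(PeptideRecord("r", seq), cfg)
            assert p.pass_helicity == (p.helicity >= cfg.helicity_min)
            assert p.pass_uh == (p.uh >= cfg.uh_min)
            assert p.pass_ncpr == (p.basic_count >= p.length / cfg.positive_per_residues)
            assert p.pass_length == (cfg.len_min <= p.length <= cfg.len_max)


class TestFindRegion:
    def test_npy_region_with_published_scores(self):
        ext = ExternalScores({NPY_REGION: 12.0})
        region = find_region(PeptideRecord("NPY", NPY_FULL), ScreenConfig(), ext)
        assert region is not None
        assert (region.start, region.end) == (16, 36)
        assert region.sequence == NPY_REGION
        assert region.properties.all_pass
        assert region.end - region.start + 1 == 21

    def test_seventeen_mer_has_no_admissible_window(self):
        ext = ExternalScores({"x": 99.0}, fallback=BuiltinHelicity())
        assert find_region(PeptideRecord("x", "K" * 17), ScreenConfig(), ext) is None

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        cfg = ScreenConfig()
        source = BuiltinHelicity()
        checked = 0
        for _ in range(25):
            seq = random_peptide(rng, int(rng.integers(18, 61)))
            rec = PeptideRecord("r", seq)
            if evaluate(rec, cfg, source).all_pass:
                continue  # region search runs only on full-length negatives
            region = find_region(rec, cfg, source)
            expected = brute_force_region(rec, cfg, source)
            got = None if region is None else (region.start, region.end)
            assert got == expected
            checked += 1
        assert checked >= 10

    def test_region_coordinates_consistent(self):
        with pytest.raises(ValueError):
            Region(start=1, end=5, sequence="AAA", properties=None)


class TestDecisions:
    def test_full_positive_never_reports_region(self):
        ext = ExternalScores({"BMAP28": 1.6})
        res = screen_record(PeptideRecord("BMAP28", BMAP28), ScreenConfig(), ext)
        assert res.decision == "positive_full" and res.region is None

    def test_region_decision_iff_region_present(self):
        ext = ExternalScores({NPY_REGION: 12.0})
        res = screen_record(PeptideRecord("NPY", NPY_FULL), ScreenConfig(), ext)
        assert res.decision == "positive_region" and res.region is not None
        neg = screen_record(PeptideRecord("g", "G" * 20))
        assert neg.decision == "negative" and neg.region is None

    def test_overlong_peptide_goes_to_region_search(self):
        # 60-mer built from a strong positive core flanked by glycine tails
        core = "LKKLLKALKKLLKALKKL"
        seq = "G" * 21 + core + "G" * 21
        ext = ExternalScores({core: 10.0})
        res = screen_record(PeptideRecord("long", seq), ScreenConfig(), ext)
        assert res.decision == "positive_region"
        assert not res.full_length.pass_length
        assert res.region.sequence == core

    def test_monotone_under_threshold_relaxation(self):
        rng = np.random.default_rng(77)
        cfg = ScreenConfig()
        source = BuiltinHelicity()
        records = [PeptideRecord(f"r{i}", random_peptide(rng, int(rng.integers(18, 55))))
                   for i in range(10)]
        base = [screen_record(r, cfg, source).decision for r in records]
        for _ in range(50):
            relaxed = ScreenConfig(
                helicity_min=cfg.helicity_min * float(rng.uniform(0, 1)),
                uh_min=cfg.uh_min * float(rng.uniform(0, 1)),
                positive_per_residues=int(rng.integers(18, 40)),
                len_min=int(rng.integers(3, 19)),
                len_max=int(rng.integers(54, 80)),
            )
            for rec, before in zip(records, base):
                after = screen_record(rec, relaxed, source).decision
                if before.startswith("positive"):
                    assert after.startswith("positive")

    def test_batch_preserves_order_and_flags_invalid(self):
        records = [
            PeptideRecord("ok", BMAP28),
            PeptideRecord("bad", "ACDX"),
            PeptideRecord("empty", ""),
        ]
        ext = ExternalScores({"ok": 1.6}, fallback=BuiltinHelicity())
        results = screen_batch(records, ScreenConfig(), ext)
        assert [r.record_id for r in results] == ["ok", "bad", "empty"]
        assert results[0].decision == "positive_full"
        assert results[1].invalid and results[1].decision == "negative"
        assert results[2].invalid and results[2].decision == "negative"

    def test_empty_batch(self):
        assert screen_batch([]) == []

    def test_determinism(self):
        rng = np.random.default_rng(5)
        records = [PeptideRecord(f"r{i}", random_peptide(rng, 30)) for i in range(5)]
        a = screen_batch(records)
        b = screen_batch([dataclasses.replace(r) for r in records])
        assert a == b


class TestConfigValidation:
    def test_len_min_exceeding_len_max_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(len_min=55, len_max=54)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(uh_min=-0.1)
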