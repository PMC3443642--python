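import numpy as np
import pytest

from rhmap import io
from rhmap.io import DELETED, INFORMATIVE, MISSING
from rhmap.mapping import classify_lines, retention_frequency
from rhmap.simulate import (
    SimBin,
    SimConfig,
    adjacent_discordance_expectation,
    study_preset,
    per_line_bin_deletion_fractions,
    simulate_panel,
    truth_map,
)


def test_bit_reproducible():
    a = simulate_panel(SimConfig(seed=123))
    b = simulate_panel(SimConfig(seed=123))
    assert np.array_equal(a.matrix.calls, b.matrix.calls)
    assert a.truth.deletions == b.truth.deletions
    assert a.truth.cm_by_bin == b.truth.cm_by_bin
    c = simulate_panel(SimConfig(seed=124))
    assert not np.array_equal(a.matrix.calls, c.matrix.calls)


def test_panel_shape_matches_study_conditions():
    panel = simulate_panel(study_preset(0))
    assert panel.matrix.n_lines == 92
    assert panel.matrix.n_markers == 540
    assert len(panel.bins) == 11
    classes = panel.truth.line_classes
    assert classes.count("INTACT") == 13
    assert classes.count("WHOLE_LOSS") == 9
    assert classes.count("SUPRA_ARM_LOSS") == 8
    assert classes.count("INFORMATIVE") == 62


def test_single_planted_deletion_scored_exactly():
    bins = (SimBin("A", "S", 0.0, 1.0, 100.0, 1.0, 10),)
    cfg = SimConfig(
        seed=1, n_lines=1, bins=bins, class_mix=(0, 0, 0, 1),
        lam=0.0, mu=10.0, eps=0.0, missing_rate=0.0,
    )
    panel = simulate_panel(cfg)
    # lam = 0: no spontaneous deletions; plant one covering markers 5-9
    # (positions 45..95) directly through the truth pathway
    calls = panel.matrix.calls.copy()
    assert (calls == 1).all()
    pos = panel.truth.positions_mb
    covered = (pos >= 50.0) & (pos <= 95.0)
    calls[0, covered] = DELETED
    assert covered.sum() == 5
    assert list(np.flatnonzero(calls[0] == DELETED)) == [5, 6, 7, 8, 9]


def test_informative_retention_range():
    # lines carrying ordinary deletions sit in the documented retention
    # window (supra-arm remnants and whole losses fall below it)
    panel = simulate_panel(study_preset(3))
    rets = np.array(
        [
            retention_frequency(panel.matrix.calls[i])
            for i, c in enumerate(panel.truth.line_classes)
            if c == INFORMATIVE
        ]
    )
    assert rets.min() >= 0.5
    # a few lines draw no marker-visible deletion (Poisson zero class) and
    # sit at exactly 1.0; the bulk shows partial loss
    assert np.mean(rets <= 0.999) >= 0.8


def test_deletion_frequency_flat_across_openness():
    # the per-marker deletion probability is lam*mu to first order,
    # independent of openness: bin means agree within Monte-Carlo error
    bins = (
        SimBin("open", "S", 0.0, 1.0, 200.0, 3.0, 50),
        SimBin("closed", "L", 0.0, 1.0, 200.0, 1 / 3.0, 50),
    )
    cfg = SimConfig(
        seed=2, n_lines=3000, bins=bins, class_mix=(0, 0, 0, 1),
        lam=0.004, mu=20, eps=0.0, missing_rate=0.0,
    )
    panel = simulate_panel(cfg)
    freq = (panel.matrix.calls == DELETED).mean(axis=0)
    open_mean = freq[np.array(panel.truth.marker_bins) == "open"].mean()
    closed_mean = freq[np.array(panel.truth.marker_bins) == "closed"].mean()
    expected = 1 - np.exp(-cfg.lam * cfg.mu)
    assert open_mean == pytest.approx(expected, abs=0.01)
    assert closed_mean == pytest.approx(expected, abs=0.01)


def test_discordance_matches_closed_form_at_large_n():
    # Monte-Carlo validation of the analytic adjacent-pair discordance
    cfg = SimConfig(
        seed=8, n_lines=5000, class_mix=(0, 0, 0, 1),
        eps=0.0, missing_rate=0.0, markers_per_mb=0.15,
    )
    panel = simulate_panel(cfg)
    calls = panel.matrix.calls
    obs = (calls[:, :-1] != calls[:, 1:]).mean(axis=0)
    exp = adjacent_discordance_expectation(
        cfg, panel.truth.positions_mb, panel.truth.marker_bins
    )
    se = np.sqrt(exp * (1 - exp) / cfg.n_lines)
    z = (obs - exp) / se
    assert np.mean(np.abs(z) <= 3) >= 0.98
    assert abs(z.mean()) < 0.5


def test_openness_scaling_of_counts_and_sizes():
    # deletion number grows with openness, size shrinks (regression slopes)
    omegas = [0.4, 0.8, 1.6, 3.2]
    counts, sizes = [], []
    for om in omegas:
        bins = (SimBin("b", "S", 0.0, 1.0, 300.0, om, 60),)
        cfg = SimConfig(
            seed=int(om * 10), n_lines=400, bins=bins, class_mix=(0, 0, 0, 1),
            lam=0.003, mu=20, eps=0.0, missing_rate=0.0,
        )
        panel = simulate_panel(cfg)
        n_del = np.mean([len(d) for d in panel.truth.deletions.values()])
        lens = [hi - lo for d in panel.truth.deletions.values() for lo, hi in d]
        counts.append(n_del)
        sizes.append(np.mean(lens))
    assert np.all(np.diff(counts) > 0)
    assert np.all(np.diff(sizes) < 0)
    # count scales ~linearly in omega; size ~1/omega (within 25%)
    assert counts[-1] / counts[0] == pytest.approx(8.0, rel=0.25)
    assert sizes[0] / sizes[-1] == pytest.approx(8.0, rel=0.35)


def test_genetic_map_tracks_openness():
    panel = simulate_panel(study_preset(5))
    cm = panel.truth.cm_by_bin
    oms = {b.name: b.openness for b in panel.truth.config.bins}
    sizes = {b.name: b.size_mb for b in panel.truth.config.bins}
    co = np.array([cm[b] / sizes[b] for b in cm])
    om = np.array([oms[b] for b in cm])
    assert np.corrcoef(co, om)[0, 1] > 0.9


def test_truth_map_layout(preset_panel):
    rh, spans, res = truth_map(preset_panel)
    assert rh.n_loci == preset_panel.matrix.n_markers
    assert [g.rep for g in rh.loci] == preset_panel.truth.marker_ids
    assert set(spans) == {b.bin_name for b in preset_panel.bins}
    for name, (lo, hi) in spans.items():
        assert hi >= lo
        if res[name] is not None:
            assert res[name] > 0


def test_per_line_bin_fraction_structure(preset_panel):
    classes = classify_lines(preset_panel.matrix, preset_panel.truth.marker_arms)
    mask = [c == INFORMATIVE for c in classes]
    x, bins = per_line_bin_deletion_fractions(
        preset_panel.matrix, preset_panel.truth.marker_bins, mask
    )
    assert x.shape == (sum(mask), 11)
    assert np.nanmax(x) <= 1.0 and np.nanmin(x) >= 0.0


def test_duplicate_genotyping_noise_channels():
    bins = (SimBin("A", "S", 0.0, 1.0, 100.0, 1.0, 200),)
    base = dict(n_lines=200, bins=bins, class_mix=(1, 0, 0, 0), lam=0.0, mu=10.0)
    noisy = simulate_panel(SimConfig(seed=3, eps=0.05, missing_rate=0.0, **base))
    frac_missing = (noisy.matrix.calls == MISSING).mean()
    frac_flipped = (noisy.matrix.calls == DELETED).mean()
    # discordant duplicates (2 eps (1-eps)) become missing; flips need both
    # reads wrong (eps^2)
    assert frac_missing == pytest.approx(2 * 0.05 * 0.95, abs=0.01)
    assert frac_flipped == pytest.approx(0.05**2, abs=0.003)
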