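"""oTRF binning: worked clustering cases, range filtering, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trflp.binning import (
    BinningConfig,
    TRFMultiset,
    bin_profile,
    cluster_moving_average,
    filter_size_range,
)
from trflp.refdigest import FragmentProfile, TerminalFragment
from trflp.taxonomy import NA_LINEAGE


@pytest.mark.parametrize(
    "entries, expected",
    [
        # canonical printed cases: one bin each
        ({70: 2, 71: 2, 72: 1, 73: 4}, [(72, 9)]),
        ({235: 60, 237: 1}, [(236, 61)]),
        # weighted mean 6322/24 = 263.42 -> nearest even 264
        ({262: 7, 263: 11, 265: 1, 266: 5}, [(264, 24)]),
        ({100: 1}, [(100, 1)]),
        # gap 3 splits chains
        ({100: 1, 103: 1}, [(100, 1), (102, 1)]),
    ],
)
def test_cluster_moving_average_worked_cases(entries, expected):
    clusters = cluster_moving_average(TRFMultiset(entries=entries))
    assert [(c.label, c.weight) for c in clusters] == expected


def test_exact_tie_rounds_to_lower_even_label():
    # singleton at an odd size is equidistant between two even labels
    (c,) = cluster_moving_average(TRFMultiset(entries={73: 5}))
    assert c.label == 72


def test_filter_size_range_is_inclusive_at_both_ends():
    ms = TRFMultiset(entries={49: 1, 50: 1, 640: 1, 641: 1})
    kept = filter_size_range(ms, BinningConfig())
    assert sorted(kept.entries) == [50, 640]
    empty = filter_size_range(TRFMultiset(entries={10: 1}), BinningConfig())
    assert empty.entries == {}
    inside = filter_size_range(TRFMultiset(entries={100: 2.5}), BinningConfig())
    assert inside.entries == {100: 2.5}


def test_binning_config_validation():
    with pytest.raises(ValueError):
        BinningConfig(window=0)
    with pytest.raises(ValueError):
        BinningConfig(min_bp=600, max_bp=50)
    with pytest.raises(ValueError):
        BinningConfig(label_rounding="stochastic")


multisets = st.dictionaries(
    st.integers(min_value=50, max_value=640),
    st.integers(min_value=1, max_value=60),
    min_size=1,
    max_size=50,
)


@given(multisets)
def test_cluster_invariants_on_random_multisets(entries):
    """Weight conservation, span <= 2w, even labels, label within one bp of
    the member range."""
    cfg = BinningConfig()
    clusters = cluster_moving_average(TRFMultiset(entries=entries), cfg)
    assert abs(sum(c.weight for c in clusters) - sum(entries.values())) < 1e-9
    labels = [c.label for c in clusters]
    assert labels == sorted(labels)
    for c in clusters:
        lo, hi = c.span
        assert hi - lo <= 2 * cfg.window
        assert c.label % 2 == 0
        assert lo - 1 <= c.label <= hi + 1


@given(multisets)
def test_clustering_is_stable_when_labels_are_well_separated(entries):
    """Re-clustering the produced labels reproduces them whenever they are
    pairwise more than one window apart (adjacent even labels re-chain by
    construction of the +-w scheme, so the unqualified form cannot hold)."""
    cfg = BinningConfig()
    clusters = cluster_moving_average(TRFMultiset(entries=entries), cfg)
    labels = [c.label for c in clusters]
    if all(b - a > cfg.window for a, b in zip(labels, labels[1:])):
        again = cluster_moving_average(
            TRFMultiset(entries={l: 1.0 for l in labels}), cfg
        )
        assert [c.label for c in again] == labels


def _three_taxon_profile():
    frags = [
        TerminalFragment(record_id=f"r{i}", length=size, unrestricted=False,
                         lineage=NA_LINEAGE)
        for i, size in enumerate((100, 200, 300))
    ]
    return FragmentProfile(enzyme="AluI", fragments=frags, dataset_id="fix")


def test_bin_profile_three_planted_taxa_three_bins():
    table = bin_profile(_three_taxon_profile())
    assert table.labels == [100, 200, 300]
    assert list(table.abundances["fix"]) == [1.0, 1.0, 1.0]


def test_bin_profile_identical_samples_give_identical_columns():
    ra = {120: 40.0, 240: 60.0}
    samples = {
        "s1": TRFMultiset.from_abundances(ra),
        "s2": TRFMultiset.from_abundances(ra),
    }
    table = bin_profile(samples, normalise=True)
    assert np.allclose(table.abundances["s1"], table.abundances["s2"])
    assert np.allclose(table.abundances.sum(axis=0), 100.0)


def test_bin_profile_normalised_columns_sum_to_100():
    rng = np.random.default_rng(0)
    samples = {
        f"s{k}": TRFMultiset.from_abundances(
            {int(s): float(h) for s, h in zip(
                rng.choice(np.arange(50, 641), size=12, replace=False),
                rng.uniform(1, 500, size=12))}
        )
        for k in range(4)
    }
    table = bin_profile(samples, normalise=True)
    assert np.allclose(table.abundances.sum(axis=0), 100.0, atol=1e-6)


def test_bin_profile_empty_sample_leaves_zero_column(caplog):
    samples = {
        "ok": TRFMultiset.from_abundances({100: 10.0}),
        "empty": TRFMultiset.from_abundances({10: 5.0}),  # outside range
    }
    table = bin_profile(samples, normalise=True)
    assert table.abundances["empty"].sum() == 0.0
    assert np.isclose(table.abundances["ok"].sum(), 100.0)


def test_bin_profile_per_sample_mode_matches_pooled_on_clean_data():
    ra = {100: 30.0, 200: 70.0}
    samples = {"s1": TRFMultiset.from_abundances(ra)}
    pooled = bin_profile(samples, mode="pooled")
    per = bin_profile(samples, mode="per-sample")
    assert pooled.abundances.equals(per.abundances)


def test_bin_profile_rejects_unknown_mode():
    with pytest.raises(ValueError, match="mode"):
        bin_profile({"s": TRFMultiset.from_abundances({100: 1.0})}, mode="global")


def test_unrestricted_fragments_survive_binning_flagged():
    frags = [
        TerminalFragment(record_id="u", length=636, unrestricted=True,
                         lineage=NA_LINEAGE),
        TerminalFragment(record_id="c", length=100, unrestricted=False,
                         lineage=NA_LINEAGE),
    ]
    profile = FragmentProfile(enzyme="AluI", fragments=frags)
    table = bin_profile(profile)
    flags = {c.label: c.unrestricted for c in table.clusters}
    assert flags == {100: False, 636: True}
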