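import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctpos.expression import (
    ChromosomeAnnotation,
    DeregulationProfile,
    GeneRecord,
    density_correlation,
    filter_deregulated,
    gene_ids,
    overlap,
    percent_deregulation,
)


def _gene(gid, fc, p, chrom="1"):
    return GeneRecord(gene_id=gid, chromosome=chrom, fold_change=fc, p_value=p)


@pytest.mark.parametrize(
    "fc,p,bucket",
    [
        (2.96, 0.01, "up"),       # clearly deregulated, upregulated
        (1.99, 0.001, None),      # below the inclusive |FC| >= 2 cutoff
        (-2.0, 0.05, None),       # p cutoff is strict: 0.05 is excluded
        (-2.0, 0.049, "down"),
        (2.0, 0.0499, "up"),      # |FC| cutoff is inclusive
    ],
)
def test_filter_boundary_conventions(fc, p, bucket):
    up, down = filter_deregulated([_gene("g", fc, p), _gene("ref", 1.1, 0.9)])
    if bucket == "up":
        assert [g.gene_id for g in up] == ["g"] and down == []
    elif bucket == "down":
        assert [g.gene_id for g in down] == ["g"] and up == []
    else:
        assert up == [] and down == []


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(-6, 6).filter(lambda v: abs(v) > 1e-6),
            st.floats(0, 1),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_filter_is_idempotent_and_disjoint(rows):
    table = [_gene(f"g{i}", fc, p) for i, (fc, p) in enumerate(rows)]
    up, down = filter_deregulated(table)
    assert gene_ids(up).isdisjoint(gene_ids(down))
    if up + down:
        up2, down2 = filter_deregulated(up + down)
        assert up2 == up and down2 == down


def test_overlap_reproduces_printed_knockdown_totals():
    """276 of 298 and 279 of 301 unique with 22 shared — exact arithmetic."""
    a = {f"a{i}" for i in range(276)} | {f"c{i}" for i in range(22)}
    b = {f"b{i}" for i in range(279)} | {f"c{i}" for i in range(22)}
    assert (len(a), len(b)) == (298, 301)
    assert overlap(a, b) == (276, 279, 22)


@settings(max_examples=50, derandomize=True)
@given(st.sets(st.integers(0, 200)), st.sets(st.integers(0, 200)))
def test_overlap_partitions_the_union(a, b):
    a = {str(v) for v in a}
    b = {str(v) for v in b}
    ua, ub, common = overlap(a, b)
    assert ua + common == len(a)
    assert ub + common == len(b)
    assert ua + ub + common == len(a | b)
    if a == b:
        assert (ua, ub, common) == (0, 0, len(a))


def _annotation():
    return [
        ChromosomeAnnotation("1", 1400, 249.0),
        ChromosomeAnnotation("18", 1000, 78.0),
        ChromosomeAnnotation("19", 2188, 59.0),
    ]


def test_percent_deregulation_arithmetic_and_strict_threshold():
    dereg = [_gene(f"u{i}", 2.5, 0.01, "1") for i in range(14)]
    dereg += [_gene(f"d{i}", -3.0, 0.01, "18") for i in range(7)]
    profile = percent_deregulation(dereg, _annotation())
    # 14/1400 -> 1.0 %, significant (> 0.7 strict)
    assert profile.percent_dereg["1"] == pytest.approx(1.0)
    assert profile.significant["1"]
    # 7/1000 -> exactly 0.7 %, NOT significant (strict >)
    assert profile.percent_dereg["18"] == pytest.approx(0.7)
    assert not profile.significant["18"]
    # untouched chromosome -> 0 %, not significant
    assert profile.percent_dereg["19"] == 0.0
    assert not profile.significant["19"]


def test_unknown_chromosome_error_names_the_gene():
    with pytest.raises(KeyError, match="ORPHAN"):
        percent_deregulation([_gene("ORPHAN", 2.5, 0.01, "21")], _annotation())


def test_gene_record_validation():
    with pytest.raises(ValueError):
        _gene("g", 0.0, 0.01)
    with pytest.raises(ValueError):
        _gene("g", 2.0, 1.5)


def test_density_correlation_is_one_on_a_planted_linear_relation():
    ann = [ChromosomeAnnotation(str(i), 100 * i, 100.0) for i in range(1, 11)]
    profile = DeregulationProfile(condition="t")
    for a in ann:
        profile.percent_dereg[a.chromosome] = 0.5 + 0.3 * a.gene_density
    assert density_correlation(profile, ann) == pytest.approx(1.0, abs=1e-12)


def test_density_correlation_equals_squared_pearson():
    rng = np.random.default_rng(3)
    ann = [ChromosomeAnnotation(str(i), int(v), 100.0)
           for i, v in enumerate(rng.integers(200, 4000, size=12), start=1)]
    profile = DeregulationProfile(condition="t")
    y = rng.uniform(0, 2, size=12)
    for a, v in zip(ann, y):
        profile.percent_dereg[a.chromosome] = float(v)
    r2 = density_correlation(profile, ann)
    x = np.array([a.gene_density for a in ann])
    assert r2 == pytest.approx(float(np.corrcoef(x, y)[0, 1] ** 2), abs=1e-12)


def test_density_correlation_null_relation_rarely_exceeds_low_r2():
    """With no planted relation across 24 chromosomes, r² stays < 0.2 in at
    least 90 % of seeded replicates."""
    hits = 0
    n_rep = 50
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        ann = [ChromosomeAnnotation(str(i), int(v), 100.0)
               for i, v in enumerate(rng.integers(200, 4000, size=24), start=1)]
        profile = DeregulationProfile(condition="t")
        for a in ann:
            profile.percent_dereg[a.chromosome] = float(rng.uniform(0, 2))
        if density_correlation(profile, ann) < 0.2:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_density_correlation_rejects_degenerate_inputs():
    ann = [ChromosomeAnnotation(str(i), 1000, 100.0) for i in range(1, 5)]
    profile = DeregulationProfile(condition="t")
    for a in ann:
        profile.percent_dereg[a.chromosome] = 1.0
    with pytest.raises(ValueError, match="variance"):
        density_correlation(profile, ann)
    with pytest.raises(ValueError, match="3"):
        density_correlation(profile, ann[:2])
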