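import numpy as np
import pandas as pd
import pytest

from rcaspot.stats import (
    compare_to_reference,
    composition_table,
    fluorescence_gate,
    linear_fit,
    linkage_table,
    log_transform,
    spearman_matrix,
    ward_cluster,
)


def brute_force_ward_d2(X):
    """O(n^3) Lance–Williams ward.D2 agglomeration (squared-distance update,
    heights reported on the distance scale).  Independent of scipy."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    # squared Euclidean distances between singletons
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    merges = []
    next_id = n
    for step in range(n - 1):
        best = None
        slots = sorted(active)
        for ai in range(len(slots)):
            for bi in range(ai + 1, len(slots)):
                i, j = slots[ai], slots[bi]
                if best is None or d2[i, j] < best[0] - 1e-12:
                    best = (d2[i, j], i, j)
        _, i, j = best
        (ci, ni), (cj, nj) = active[i], active[j]
        merges.append((min(ci, cj), max(ci, cj), np.sqrt(d2[i, j]), ni + nj))
        # ward.D2 update on squared distances
        for k in slots:
            if k in (i, j):
                continue
            nk = active[k][1]
            tot = ni + nj + nk
            d2[i, k] = d2[k, i] = (
                (ni + nk) / tot * d2[i, k]
                + (nj + nk) / tot * d2[j, k]
                - nk / tot * d2[i, j]
            )
        active[i] = (next_id, ni + nj)
        del active[j]
        next_id += 1
    return merges


def rank_then_pearson(table):
    """Spearman oracle: average-rank each column, then Pearson correlations."""
    ranks = table.rank(method="average")
    return np.corrcoef(ranks.to_numpy().T)


def test_log_transform_values_and_roundtrip(rng):
    counts = pd.DataFrame(rng.integers(0, 50, (20, 5)))
    logged = log_transform(counts)
    assert logged.iloc[0, 0] == np.log2(counts.iloc[0, 0] + 1)
    recovered = (2.0**logged - 1).round().astype(int)
    pd.testing.assert_frame_equal(recovered, counts.astype(int))
    assert log_transform(pd.DataFrame({"a": [7]})).iloc[0, 0] == 3.0
    with pytest.raises(ValueError):
        log_transform(pd.DataFrame({"a": [-1]}))


def test_ward_identical_cells_merge_at_zero():
    X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
    Z, _ = ward_cluster(X, n_clusters=1)
    assert Z[0, 2] == 0.0


def test_ward_recovers_two_separated_groups(rng):
    a = rng.normal(0, 0.5, (15, 4))
    b = rng.normal(10, 0.5, (12, 4))
    X = pd.DataFrame(np.vstack([a, b]))
    _, ids = ward_cluster(X, n_clusters=2)
    assert len(set(ids[:15])) == 1 and len(set(ids[15:])) == 1
    assert ids.iloc[0] != ids.iloc[-1]


def test_ward_matches_brute_force_oracle_small_n(rng):
    for _ in range(12):
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, 3))
        Z, _ = ward_cluster(pd.DataFrame(X))
        oracle = brute_force_ward_d2(X)
        got = [(int(min(r[0], r[1])), int(max(r[0], r[1]))) for r in Z]
        exp = [(m[0], m[1]) for m in oracle]
        assert got == exp
        np.testing.assert_allclose(Z[:, 2], [m[2] for m in oracle], rtol=1e-8)


def test_ward_heights_nondecreasing(rng):
    X = pd.DataFrame(rng.normal(size=(40, 6)))
    Z, _ = ward_cluster(X, n_clusters=3)
    assert (np.diff(Z[:, 2]) >= -1e-12).all()
    lt = linkage_table(Z)
    assert list(lt.columns) == ["step", "a", "b", "height"]


def test_ward_too_few_cells_errors():
    with pytest.raises(ValueError):
        ward_cluster(pd.DataFrame([[1.0]]), n_clusters=1)
    with pytest.raises(ValueError):
        ward_cluster(pd.DataFrame(np.eye(3)), n_clusters=5)


def test_spearman_matches_rank_then_pearson_with_ties(rng):
    table = pd.DataFrame(rng.integers(0, 5, (10, 4)), columns=list("abcd"))
    rho = spearman_matrix(table)
    np.testing.assert_allclose(rho.to_numpy(), rank_then_pearson(table), atol=1e-12)
    assert (np.diag(rho) == 1).all()
    np.testing.assert_allclose(rho, rho.T)


def test_spearman_self_negation_and_monotone_invariance(rng):
    x = rng.normal(size=30)
    table = pd.DataFrame({"x": x, "neg": -x, "exp": np.exp(x)})
    rho = spearman_matrix(table)
    assert rho.loc["x", "neg"] == pytest.approx(-1.0)
    assert rho.loc["x", "exp"] == pytest.approx(1.0)  # strictly monotone map


def test_spearman_constant_column_is_missing_not_zero(rng):
    table = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
    rho = spearman_matrix(table)
    assert np.isnan(rho.loc["x", "c"])
    assert rho.loc["x", "x"] == 1.0


def test_linear_fit_exact_line_and_hand_computed_points():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert linear_fit(x, 2 * x) == pytest.approx((2.0, 0.0, 1.0))
    # 5 points, normal equations by hand: x=[0..4], y=[1,3,2,5,4]
    x5 = np.arange(5.0)
    y5 = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    slope = ((x5 - 2) * (y5 - 3)).sum() / ((x5 - 2) ** 2).sum()
    intercept = 3 - slope * 2
    got = linear_fit(x5, y5)
    assert got[0] == pytest.approx(slope) and got[1] == pytest.approx(intercept)


def test_linear_fit_noise_has_low_r2(rng):
    x = rng.normal(size=1000)
    y = rng.normal(size=1000)
    assert linear_fit(x, y)[2] < 0.1


def test_linear_fit_degenerate_x():
    with pytest.raises(ValueError, match="zero variance"):
        linear_fit(np.ones(5), np.arange(5.0))


def test_fluorescence_gate_threshold_is_control_max(rng):
    control = pd.Series([100.0, 400.0, 500.0])
    cells = pd.Series([501.0, 500.0, 10.0], index=[1, 2, 3])
    gate = fluorescence_gate(cells, control)
    assert gate.tolist() == [True, False, False]
    # every control cell is negative against its own threshold
    assert not fluorescence_gate(control, control).any()
    with pytest.raises(ValueError, match="empty"):
        fluorescence_gate(cells, pd.Series(dtype=float))


def test_fluorescence_gate_recovers_reporter_cells(rng):
    control = pd.Series(rng.uniform(0, 500, 200))
    on = pd.Series(rng.uniform(1100, 2000, 50))  # > 2x control max
    off = pd.Series(rng.uniform(0, 500, 50))
    rid = pd.concat([on, off], ignore_index=True)
    gate = fluorescence_gate(rid, control)
    assert gate[:50].all() and not gate[50:].any()


def test_compare_to_reference_limits(rng):
    means = pd.Series(rng.uniform(0, 5, 12), index=[f"g{i}" for i in range(12)])
    rho, paired = compare_to_reference(means, means * 3 + 1)
    assert rho == pytest.approx(1.0)
    rho_rev, _ = compare_to_reference(means, -means)
    assert rho_rev == pytest.approx(-1.0)
    assert len(paired) == 12
    with pytest.raises(ValueError, match="shared genes"):
        compare_to_reference(means[:2], means[:2])


def test_compare_to_reference_monotone_construction(rng):
    lam = pd.Series(np.linspace(0.5, 20, 12), index=[f"g{i}" for i in range(12)])
    observed = np.log2(lam + 1) + rng.normal(0, 0.1, 12)
    reference = np.log2(3 * lam + 1)  # monotone in the true rates
    rho, _ = compare_to_reference(observed, reference)
    assert rho >= 0.9


def test_composition_table_normalizations(rng):
    labels = pd.Series(rng.choice(["A", "B", "NA"], 200))
    regions = pd.Series(rng.choice(["prox", "dist"], 200))
    by_type, by_region = composition_table(labels, regions)
    np.testing.assert_allclose(by_type.sum(axis=1), 100.0, atol=1e-9)
    np.testing.assert_allclose(by_region.sum(axis=1), 100.0, atol=1e-9)
    # brute-force tally check
    tally = pd.crosstab(labels, regions)
    for t in tally.index:
        for r in tally.columns:
            assert by_type.loc[t, r] == pytest.approx(
                100 * tally.loc[t, r] / tally.loc[t].sum()
            )
    assert "NA" in by_region.columns


def test_marker_expression_table_percentages(rng):
    from rcaspot.stats import marker_expression_table

    counts = pd.DataFrame(
        {"g1": [0, 2, 5, 0], "g2": [1, 1, 0, 0]},
        index=pd.Index([1, 2, 3, 4], name="cell_id"),
    )
    labels = pd.Series(["A", "A", "B", "B"], index=counts.index)
    tab = marker_expression_table(labels, counts)
    assert tab.loc["A", "g1"] == 50.0 and tab.loc["A", "g2"] == 100.0
    assert tab.loc["B", "g1"] == 50.0 and tab.loc["B", "g2"] == 0.0


def test_composition_single_region_type():
    labels = pd.Series(["A"] * 5 + ["B"] * 5)
    regions = pd.Series(["x"] * 5 + ["y"] * 5)
    by_type, by_region = composition_table(labels, regions)
    assert by_type.loc["A", "x"] == 100.0 and by_type.loc["A", "y"] == 0.0
    assert by_region.loc["x", "A"] == 100.0
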