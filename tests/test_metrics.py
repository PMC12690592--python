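import pytest

from clmrl import chem
from clmrl.metrics import (
    ChemFilterConfig,
    MetricLedger,
    aggregate_benchmark,
    chem_filter,
    diverse_top10,
    sediv,
    top10_avg,
    uniqueness,
    validity,
)


# ------------------------------------------------------------------ validity

def test_validity_fractions():
    assert validity(["CCO", "CCN"]) == 1.0
    assert validity(["CCO", "C(C"]) == 0.5
    assert validity(["C(C", ")("]) == 0.0
    with pytest.raises(ValueError):
        validity([])


# ----------------------------------------------------------------- top10 avg

def test_top10_avg_constant():
    records = [(f"{'C' * (i + 1)}O", 0.7) for i in range(10)]
    assert top10_avg(records) == pytest.approx(0.7)


def test_top10_avg_eleven_records():
    records = [(f"{'C' * (i + 1)}O", i / 10) for i in range(11)]
    assert top10_avg(records) == pytest.approx(0.55)


def test_top10_avg_dedups_same_molecule():
    # same molecule written two ways plus one distinct
    records = [("CCO", 0.9), ("OCC", 0.9), ("CCN", 0.1)]
    assert top10_avg(records) == pytest.approx(0.5)


# ---------------------------------------------------------------- uniqueness

def test_uniqueness_cases():
    assert uniqueness(["CCO", "CCN", "CCC"]) == 1.0
    assert uniqueness(["CCO"] * 4) == 0.25
    assert uniqueness(["CCO", "OCC", "C(C)O"]) == pytest.approx(1 / 3)


# ----------------------------------------------------------------- top10 AUC

def _brute_force_auc(batches):
    """Independent recomputation: replay the stream, cumulative dedup best-10
    mean at each boundary, trapezoid over molecules consumed."""
    best = {}
    points = []
    consumed = 0
    for batch in batches:
        for canonical, reward in batch:
            consumed += 1
            if canonical is not None:
                if canonical not in best or reward > best[canonical]:
                    best[canonical] = reward
        top = sorted(best.values(), reverse=True)[:10]
        points.append((consumed, sum(top) / len(top) if top else 0.0))
    area = points[0][0] * points[0][1]
    for (na, va), (nb, vb) in zip(points, points[1:]):
        area += (nb - na) * 0.5 * (va + vb)
    return area / points[-1][0]


def test_auc_constant_curve_is_identity():
    ledger = MetricLedger(budget=100)
    for step in range(4):
        ledger.record_batch([(f"M{step}_{i}", 0.42) for i in range(25)], step)
    assert ledger.top10_auc() == pytest.approx(0.42, abs=1e-12)


def test_auc_streaming_matches_brute_force(rng):
    """Streaming value equals an independent recomputation over 1,000 random
    records, to 1e-12."""
    ledger = MetricLedger(budget=1000)
    pool = [f"M{i}" for i in range(300)]
    batches = []
    for step in range(20):
        batch = []
        for _ in range(50):
            if rng.random() < 0.1:
                batch.append((None, 0.0))
            else:
                batch.append((pool[int(rng.integers(len(pool)))], float(rng.random())))
        batches.append(batch)
        ledger.record_batch(batch, step)
    assert ledger.top10_auc() == pytest.approx(_brute_force_auc(batches), abs=1e-12)


def test_auc_step_function_at_half_budget():
    ledger = MetricLedger(budget=1000)
    for step in range(20):
        val = 0.0 if step < 10 else 1.0
        ledger.record_batch([(f"M{step}_{i}", val) for i in range(50)], step)
    assert ledger.top10_auc() == pytest.approx(0.5, abs=50 / 1000)


def test_ledger_guards():
    ledger = MetricLedger(budget=2)
    ledger.record("CCO", 0.5, 0)
    ledger.record("CCN", 0.5, 0)
    with pytest.raises(ValueError):
        ledger.record("CCC", 0.5, 0)
    with pytest.raises(ValueError):
        MetricLedger(budget=5).top10_auc()


def test_ledger_running_top10_non_decreasing(rng):
    ledger = MetricLedger(budget=500)
    for step in range(10):
        ledger.record_batch(
            [(f"M{int(rng.integers(100))}", float(rng.random())) for _ in range(50)], step
        )
    values = [v for _, v in ledger.curve]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


# ----------------------------------------------------------------- chem filter

WIDE = ChemFilterConfig(alerts=(), logp_range=(-5, 5), mol_weight_range=(0, 500),
                        max_rotatable_bonds=10)


def test_chem_filter_ethanol_passes():
    assert chem_filter(["CCO"], WIDE) == [True]


def test_chem_filter_alert_fails():
    cfg = ChemFilterConfig(logp_range=(-5, 5), mol_weight_range=(0, 500))
    assert chem_filter(["O=[N+]([O-])c1ccccc1"], cfg) == [False]


def test_chem_filter_property_out_of_range():
    cfg = ChemFilterConfig(alerts=(), mol_weight_range=(0.0, 100.0))
    assert chem_filter(["CCCCCCCCCCCC"], cfg) == [False]
    assert chem_filter(["C(C"], WIDE) == [False]


def test_chem_filter_invalid_smarts():
    cfg = ChemFilterConfig(alerts=("[[bad",))
    with pytest.raises(ValueError):
        chem_filter(["CCO"], cfg)


# --------------------------------------------------------------- diverse top10

def _oracle_diverse_top10(records):
    """Best molecule per scaffold group, then top 10 by reward."""
    best_per_scaffold = {}
    for smiles, reward in records:
        canonical = chem.canonical_smiles(smiles)
        if canonical is None:
            continue
        scaffold = chem.murcko_scaffold(canonical) or ""
        cur = best_per_scaffold.get(scaffold)
        if cur is None or reward > cur[1]:
            best_per_scaffold[scaffold] = (canonical, reward)
    return sorted(best_per_scaffold.values(), key=lambda t: -t[1])[:10]


def test_diverse_top10_distinct_scaffolds_equals_plain():
    rings = ["c1ccccc1", "c1ccncc1", "c1cc[nH]c1", "c1ccco1", "c1cccs1",
             "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCCC1", "C1CCCCCC1"]
    records = [(r, 0.1 * i) for i, r in enumerate(rings)]
    out = diverse_top10(records)
    assert len(out) == 10
    assert {s for s, _ in out} == {chem.canonical_smiles(r) for r in rings}


def test_diverse_top10_single_scaffold_collapses():
    records = [(f"{'C' * (i + 1)}c1ccccc1", 0.05 * i) for i in range(20)]
    out = diverse_top10(records)
    assert len(out) == 1
    assert out[0][1] == pytest.approx(0.95)


def test_diverse_top10_matches_oracle_mixed():
    records = (
        [(f"{'C' * (i + 1)}c1ccccc1", 0.06 * i) for i in range(5)]
        + [(f"{'C' * (i + 1)}c1ccncc1", 0.05 * i + 0.1) for i in range(5)]
        + [(f"{'C' * (i + 2)}O", 0.07 * i) for i in range(5)]
    )
    assert diverse_top10(records) == _oracle_diverse_top10(records)


# ---------------------------------------------------------------------- SEDiv

def test_sediv_identical_molecules():
    assert sediv(["CCO"] * 5) == pytest.approx(1 / 5)


def test_sediv_fully_dissimilar():
    # pairwise fingerprint Tanimoto of these is exactly 0
    mols = ["CCCCCC", "NNNNN", "c1ccccc1"]
    fps = [chem.morgan_fingerprint(m) for m in mols]
    for i in range(3):
        for j in range(i + 1, 3):
            assert chem.tanimoto(fps[i], fps[j]) == 0.0
    assert sediv(mols) == 1.0


def test_sediv_order_robust():
    """Result stable within +/-2 points across randomized pick orders."""
    series = [f"{'C' * (i + 1)}c1ccccc1" for i in range(40)]
    series += [f"{'C' * (i + 1)}c1ccncc1" for i in range(40)]
    series += [f"{'C' * (i + 1)}O" for i in range(40)]
    vals = [sediv(series, sample_size=120, seed=s) for s in range(10)]
    assert max(vals) - min(vals) <= 0.04


def test_sediv_empty_error():
    with pytest.raises(ValueError):
        sediv(["C(C"])


# ------------------------------------------------------------------ aggregate

def test_aggregate_benchmark_sums_tasks():
    reports = [{"validity": 0.9, "top10_auc": 0.5}, {"validity": 1.0, "top10_auc": 0.7}]
    agg = aggregate_benchmark(reports)
    assert agg == {"validity": pytest.approx(1.9), "top10_auc": pytest.approx(1.2)}
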