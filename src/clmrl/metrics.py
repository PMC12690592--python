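"""Benchmark metrics computed streaming over a fixed generation budget.

Chemistry-naive level: validity, Top-10 Avg (mean reward of the ten best
unique molecules), Top-10 AUC (budget-normalized area under the running
top-10 curve — the sample-efficiency metric), and uniqueness. Chemistry-aware
level: basic chemistry filters (substructure alerts, LogP range, molecular
weight range, rotatable-bond cap), a scaffold-diverse Top-10 variant, and
sphere-exclusion diversity (SEDiv).

The ledger ingests one record per generated molecule (canonical SMILES or an
invalid flag, its raw reward, and the step index) and closes a curve point
at each batch boundary; AUC is the trapezoidal integral of that curve over
molecules consumed, normalized so a constant curve at value r scores r.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chem


@dataclass(frozen=True)
class MoleculeRecord:
    canonical: str | None      # None = chemically invalid generation
    reward: float
    step: int


@dataclass
class MetricLedger:
    budget: int
    records: list[MoleculeRecord] = field(default_factory=list)
    curve: list[tuple[int, float]] = field(default_factory=list)  # (consumed, top10 mean)
    _best: dict[str, float] = field(default_factory=dict, repr=False)

    def record(self, canonical: str | None, reward: float, step: int) -> None:
        if len(self.records) >= self.budget:
            raise ValueError("ledger budget exhausted")
        self.records.append(MoleculeRecord(canonical, float(reward), step))
        if canonical is not None:
            prev = self._best.get(canonical)
            if prev is None or reward > prev:
                self._best[canonical] = float(reward)

    def record_batch(self, items: list[tuple[str | None, float]], step: int) -> None:
        for canonical, reward in items:
            self.record(canonical, reward, step)
        self.mark_batch()

    def mark_batch(self) -> None:
        """Close a batch boundary: append a running top-10 curve point."""
        self.curve.append((len(self.records), self._running_top10()))

    def _running_top10(self) -> float:
        if not self._best:
            return 0.0
        top = heapq.nlargest(10, self._best.values())
        return float(np.mean(top))

    # ------------------------------------------------------------- metrics

    def validity(self) -> float:
        if not self.records:
            raise ValueError("no records")
        return sum(r.canonical is not None for r in self.records) / len(self.records)

    def uniqueness(self) -> float:
        valid = [r for r in self.records if r.canonical is not None]
        if not valid:
            raise ValueError("no valid records")
        return len({r.canonical for r in valid}) / len(valid)

    def top10_avg(self) -> float:
        """Mean reward of the 10 best unique molecules (fewer if scarce)."""
        if not self._best:
            raise ValueError("no valid records")
        return float(np.mean(heapq.nlargest(10, self._best.values())))

    def top10_auc(self) -> float:
        """Budget-normalized trapezoidal AUC of the running top-10 curve.

        The curve is extended flat from 0 to the first boundary, so a
        constant reward stream at value r yields exactly r.
        """
        if not self.curve:
            raise ValueError("empty ledger")
        total = self.curve[-1][0]
        if total == 0:
            raise ValueError("no molecules recorded")
        n0, v0 = self.curve[0]
        area = n0 * v0
        for (na, va), (nb, vb) in zip(self.curve, self.curve[1:]):
            area += (nb - na) * 0.5 * (va + vb)
        return area / total

    def final_report(self) -> dict[str, float]:
        return {
            "validity": self.validity(),
            "uniqueness": self.uniqueness(),
            "top10_avg": self.top10_avg(),
            "top10_auc": self.top10_auc(),
        }

    # ----------------------------------------------------------------- I/O

    def save_curve(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.curve, columns=["molecules", "top10_mean"]).to_csv(path, index=False)

    def save_report(self, csv_path: str | Path | None = None,
                    json_path: str | Path | None = None) -> dict[str, float]:
        report = self.final_report()
        if csv_path is not None:
            import pandas as pd

            pd.DataFrame([report]).to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(report, indent=2))
        return report


# ------------------------------------------------------------ plain helpers

def validity(smiles_list: list[str]) -> float:
    if not smiles_list:
        raise ValueError("empty input")
    return sum(chem.is_valid(s) for s in smiles_list) / len(smiles_list)


def top10_avg(records: list[tuple[str, float]]) -> float:
    """Mean of the 10 highest rewards among valid, canonically unique molecules."""
    best: dict[str, float] = {}
    for smiles, reward in records:
        canonical = chem.canonical_smiles(smiles)
        if canonical is None:
            continue
        if canonical not in best or reward > best[canonical]:
            best[canonical] = reward
    if not best:
        raise ValueError("no valid records")
    return float(np.mean(heapq.nlargest(10, best.values())))


def uniqueness(smiles_list: list[str]) -> float:
    canonicals = [chem.canonical_smiles(s) for s in smiles_list]
    valid = [c for c in canonicals if c is not None]
    if not valid:
        raise ValueError("no valid molecules")
    return len(set(valid)) / len(valid)


# ------------------------------------------------------- chemistry filters

DEFAULT_ALERTS = (
    "[N+](=O)[O-]",          # nitro
    "C(=O)Cl",               # acyl halide
    "[S,s]~[S,s]",           # disulfide-like
    "[CH2][CH2][CH2][CH2][CH2][CH2][CH2][CH2]",  # long aliphatic chain
)


@dataclass(frozen=True)
class ChemFilterConfig:
    alerts: tuple[str, ...] = DEFAULT_ALERTS
    logp_range: tuple[float, float] = (-5.0, 7.5)
    mol_weight_range: tuple[float, float] = (150.0, 650.0)
    max_rotatable_bonds: int = 10

    def __post_init__(self) -> None:
        if self.logp_range[0] > self.logp_range[1]:
            raise ValueError("logp_range must be ordered")
        if self.mol_weight_range[0] > self.mol_weight_range[1]:
            raise ValueError("mol_weight_range must be ordered")


def chem_filter(smiles_list: list[str], config: ChemFilterConfig = ChemFilterConfig()) -> list[bool]:
    """Pass flags: valid, no alert match, and all properties in range."""
    flags = []
    for smiles in smiles_list:
        props = chem.basic_properties(smiles)
        if props is None:
            flags.append(False)
            continue
        if chem.matches_smarts(smiles, list(config.alerts)):
            flags.append(False)
            continue
        ok = (
            config.logp_range[0] <= props["logp"] <= config.logp_range[1]
            and config.mol_weight_range[0] <= props["mol_weight"] <= config.mol_weight_range[1]
            and props["rotatable_bonds"] <= config.max_rotatable_bonds
        )
        flags.append(ok)
    return flags


def diverse_top10(records: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Greedy top-10 with each Bemis-Murcko scaffold represented at most once.

    Molecules are visited by descending reward; one whose scaffold is
    already represented is skipped. May return fewer than 10 entries when
    scaffold variety is short.
    """
    scored: list[tuple[str, float, str]] = []
    for smiles, reward in records:
        canonical = chem.canonical_smiles(smiles)
        if canonical is None:
            continue
        scaffold = chem.murcko_scaffold(canonical) or ""
        scored.append((canonical, reward, scaffold))
    best: dict[str, tuple[str, float, str]] = {}
    for canonical, reward, scaffold in scored:
        if canonical not in best or reward > best[canonical][1]:
            best[canonical] = (canonical, reward, scaffold)
    ranked = sorted(best.values(), key=lambda t: -t[1])
    chosen: list[tuple[str, float]] = []
    seen_scaffolds: set[str] = set()
    for canonical, reward, scaffold in ranked:
        if scaffold in seen_scaffolds:
            continue
        seen_scaffolds.add(scaffold)
        chosen.append((canonical, reward))
        if len(chosen) == 10:
            break
    return chosen


def sediv(smiles_list: list[str], sample_size: int = 1000,
          similarity_threshold: float = 0.65, seed: int = 0,
          radius: int = 2, n_bits: int = 2048) -> float:
    """Sphere-exclusion diversity: fraction of a sample picked as centroids.

    Molecules are visited in a seed-randomized order; one is a new centroid
    iff its Tanimoto similarity to every existing centroid is below the
    threshold. 1 means every molecule covers a different part of chemical
    space; 1/n means one sphere covers everything.
    """
    valid = [s for s in smiles_list if chem.is_valid(s)]
    if not valid:
        raise ValueError("no valid molecules for SEDiv")
    rng = np.random.default_rng(seed)
    if len(valid) > sample_size:
        idx = rng.choice(len(valid), size=sample_size, replace=False)
        sample = [valid[i] for i in idx]
    else:
        sample = list(valid)
        rng.shuffle(sample)
    fps = [chem.morgan_fingerprint(s, radius=radius, n_bits=n_bits) for s in sample]
    centroids: list[np.ndarray] = []
    for fp in fps:
        if all(chem.tanimoto(fp, c) < similarity_threshold for c in centroids):
            centroids.append(fp)
    return len(centroids) / len(sample)


def aggregate_benchmark(per_task_reports: list[dict[str, float]]) -> dict[str, float]:
    """Sum each per-task metric (each in [0, 1]) over the configured tasks."""
    if not per_task_reports:
        raise ValueError("no task reports")
    keys = per_task_reports[0].keys()
    return {k: float(sum(rep[k] for rep in per_task_reports)) for k in keys}
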