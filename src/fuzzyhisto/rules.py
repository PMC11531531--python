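"""Wang–Mendel rule induction, rule-feature prefiltering, and fuzzy inference.

The Wang–Mendel method turns each training sample into one primitive rule:
the antecedent is the maximal-membership level of every variable, the
consequent is the sample's class, and the rule degree is the product of those
maximal memberships.  Duplicate rules collapse to one; rules with identical
antecedents but different consequents conflict and are resolved by keeping
the highest-degree rule, leaving a rule base with pairwise-distinct
antecedents.

Also here: the rule-feature prefilter (drop high-zero-fraction columns, keep
the top-k by absolute Pearson correlation with the label), max–min rule
aggregation, and centroid defuzzification over a discretized output grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import FeatureTable
from .membership import FuzzyPartition, MembershipFunction


@dataclass(frozen=True)
class FuzzyRule:
    """IF x_j is level antecedent[j] for all j THEN class ``consequent``."""

    antecedent: tuple[int, ...]
    consequent: int
    degree: float

    def __post_init__(self) -> None:
        if not (0.0 < self.degree <= 1.0 + 1e-12):
            raise ValueError(f"rule degree {self.degree} outside (0, 1]")


@dataclass
class RuleBase:
    """Non-conflicting, de-duplicated rules over per-variable partitions.

    ``provenance`` records how many rules existed at each reduction stage:
    ``primitive`` (one per training sample), ``deduplicated`` (distinct
    antecedent+consequent pairs) and ``final`` (distinct antecedents after
    conflict resolution).
    """

    rules: list[FuzzyRule]
    partitions: list[FuzzyPartition]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        antecedents = [r.antecedent for r in self.rules]
        if len(set(antecedents)) != len(antecedents):
            raise ValueError("rule base contains duplicate antecedents")
        for r in self.rules:
            if len(r.antecedent) != len(self.partitions):
                raise ValueError("antecedent arity != number of partitions")
            for level, part in zip(r.antecedent, self.partitions):
                if not (0 <= level < part.n_levels):
                    raise ValueError(f"antecedent level {level} out of range")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "partitions": [
                {
                    "variable_id": p.variable_id,
                    "domain": list(p.domain),
                    "mfs": [{"kind": m.kind, "params": _params_to_json(m)}
                            for m in p.mfs],
                }
                for p in self.partitions
            ],
            "rules": [
                {"antecedent": list(r.antecedent), "consequent": int(r.consequent),
                 "degree": float(r.degree)}
                for r in self.rules
            ],
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RuleBase":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        payload = json.loads(text)
        partitions = [
            FuzzyPartition(
                p["variable_id"],
                [MembershipFunction(m["kind"], _params_from_json(m))
                 for m in p["mfs"]],
                tuple(p["domain"]),
            )
            for p in payload["partitions"]
        ]
        rules = [FuzzyRule(tuple(r["antecedent"]), r["consequent"], r["degree"])
                 for r in payload["rules"]]
        return cls(rules, partitions, payload.get("provenance", {}))


def _params_to_json(mf: MembershipFunction):
    if mf.kind == "piecewise_linear":
        xs, ys = mf.params
        return [list(map(float, xs)), list(map(float, ys))]
    return [float(v) for v in mf.params]


def _params_from_json(m: dict) -> tuple:
    if m["kind"] == "piecewise_linear":
        xs, ys = m["params"]
        return (tuple(xs), tuple(ys))
    return tuple(m["params"])


def wang_mendel(X, y, partitions: list[FuzzyPartition]) -> RuleBase:
    """Induce a rule base from samples: one primitive rule per sample.

    Level selection is argmax membership (ties -> lower level index); the
    rule degree is the product of the selected memberships.  Identical
    (antecedent, consequent) pairs deduplicate; antecedent conflicts keep
    the maximum-degree rule (ties -> first encountered in sample order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != len(partitions):
        raise ValueError("X columns must match the number of partitions")
    n = X.shape[0]
    best: dict[tuple[int, ...], FuzzyRule] = {}
    seen_pairs: set[tuple] = set()
    for s in range(n):
        levels, degree = [], 1.0
        for j, part in enumerate(partitions):
            mu = part.memberships(X[s, j])
            lvl = int(np.argmax(mu))
            levels.append(lvl)
            degree *= float(mu[lvl])
        assert degree > 0, "sample outside all partitions despite coverage"
        ant = tuple(levels)
        seen_pairs.add((ant, int(y[s])))
        rule = FuzzyRule(ant, int(y[s]), min(degree, 1.0))
        if ant not in best or rule.degree > best[ant].degree:
            best[ant] = rule
    rules = list(best.values())
    return RuleBase(rules, list(partitions), provenance={
        "primitive": n,
        "deduplicated": len(seen_pairs),
        "final": len(rules),
    })


def prefilter_and_rank(table: FeatureTable, zero_frac_threshold: float = 0.10,
                       top_k: int = 8, seed: int = 0) -> FeatureTable:
    """Drop high-zero columns, keep the top-k by |Pearson r| with the label.

    Columns whose fraction of exact zeros exceeds ``zero_frac_threshold``
    are removed first; survivors are ranked by the absolute Pearson
    correlation between the column and the 0/1 label (point-biserial), and
    the ``top_k`` best are returned, columns ordered by decreasing |r| and
    rows shuffled with the configured seed.
    """
    if not (0 < zero_frac_threshold < 1):
        raise ValueError("zero_frac_threshold must lie in (0, 1)")
    X, y = table.matrix, table.labels.astype(float)
    zero_frac = (X == 0).mean(axis=0)
    keep = np.flatnonzero(zero_frac <= zero_frac_threshold)
    if keep.size == 0:
        raise ValueError("no columns survive the zero-fraction filter")
    if top_k > keep.size:
        raise ValueError(f"top_k={top_k} exceeds {keep.size} surviving columns")
    xk = X[:, keep]
    xc = xk - xk.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    order = np.lexsort((keep, -np.abs(r)))[:top_k]
    cols = keep[order]
    perm = np.random.default_rng(seed).permutation(len(y))
    return FeatureTable(X[np.ix_(perm, cols)], table.labels[perm],
                        [table.feature_ids[j] for j in cols])


def aggregate_maxmin(firing, consequent_sets) -> np.ndarray:
    """Max–min aggregation: per grid point, max over rules of
    min(rule activation, consequent membership).

    ``firing`` has one activation in [0, 1] per rule; ``consequent_sets`` is
    an (n_rules, n_grid) array of consequent memberships over the output
    grid.  All activations 0 yields the all-zero output set.
    """
    alpha = np.asarray(firing, dtype=float)
    sets = np.atleast_2d(np.asarray(consequent_sets, dtype=float))
    if alpha.ndim != 1 or sets.shape[0] != alpha.size:
        raise ValueError("one consequent set required per rule activation")
    if alpha.size and ((alpha < -1e-12).any() or (alpha > 1 + 1e-12).any()):
        raise ValueError("activations must lie in [0, 1]")
    if alpha.size == 0:
        return np.zeros(sets.shape[1])
    return np.max(np.minimum(alpha[:, None], sets), axis=0)


def defuzz_centroid(grid, mu) -> float:
    """Centroid of a fuzzy set over a discretized grid: ∫yμ(y)dy / ∫μ(y)dy."""
    grid = np.asarray(grid, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if grid.shape != mu.shape or grid.ndim != 1:
        raise ValueError("grid and membership vectors must match 1-D shapes")
    denom = np.trapezoid(mu, grid)
    if denom <= 0:
        raise ValueError("centroid undefined for an (almost) all-zero set")
    return float(np.trapezoid(grid * mu, grid) / denom)
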