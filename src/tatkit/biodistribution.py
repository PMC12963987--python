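"""Decay-corrected biodistribution and decay-chain activities.

Gamma-counter measurements are converted to percent injected activity
per gram of tissue (%IA/g) against a reference standard counted at a
known fraction of the injected activity.  For the therapeutic nuclide,
whose own photon emissions are impractical to count directly, the
activity of a short-lived daughter in secular equilibrium is used as a
surrogate; :func:`bateman_activity` provides the chain activities needed
to verify when equilibrium holds for any chosen counting delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Nuclide:
    name: str
    half_life_days: float
    alpha_mev: float = 0.0       # mean alpha energy per decay
    electron_mev: float = 0.0    # mean beta/conversion-electron energy per decay

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError(f"{self.name}: half-life must be positive")

    @property
    def decay_constant(self) -> float:
        """lambda = ln2 / half-life, in 1/day; zero for stable nuclides."""
        if np.isinf(self.half_life_days):
            return 0.0
        return LN2 / self.half_life_days

    @property
    def local_energy_mev(self) -> float:
        """Locally absorbed energy per decay (alpha + electrons, no photons)."""
        return self.alpha_mev + self.electron_mev


@dataclass(frozen=True)
class ChainStep:
    parent: str
    child: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("branching fraction must lie in (0, 1]")


@dataclass
class DecayChain:
    """A branched decay chain rooted at a single parent nuclide."""

    parent: str
    nuclides: dict[str, Nuclide]
    steps: list[ChainStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        edges = [(s.parent, s.child) for s in self.steps]
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate decay step in chain")
        for s in self.steps:
            if s.parent not in self.nuclides or s.child not in self.nuclides:
                raise ValueError(f"chain step {s.parent}->{s.child} references "
                                 "an unknown nuclide")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children = {}
        for s in self.steps:
            children.setdefault(s.parent, []).append(s.child)
        seen: set[str] = set()

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if node in stack:
                raise ValueError("decay chain contains a cycle")
            for child in children.get(node, []):
                visit(child, stack + (node,))
            seen.add(node)

        visit(self.parent, ())

    @property
    def members(self) -> list[str]:
        """Members in topological order starting at the parent."""
        order = [self.parent]
        for s in self.steps:
            if s.child not in order:
                order.append(s.child)
        return order

    def paths_to(self, member: str) -> list[list[ChainStep]]:
        """All branch paths from the chain parent to ``member``."""
        if member == self.parent:
            return [[]]
        paths = []
        for s in self.steps:
            if s.child == member:
                for prefix in self.paths_to(s.parent):
                    paths.append(prefix + [s])
        return paths

    def path_probability(self, member: str) -> float:
        """Probability that a parent decay eventually reaches ``member``."""
        return sum(float(np.prod([s.fraction for s in p]) if p else 1.0)
                   for p in self.paths_to(member))

    def energy_per_parent_decay_mev(self, exclude_after: str | None = None) -> float:
        """Locally absorbed energy per parent decay at secular equilibrium.

        Sums each member's alpha + electron energy weighted by the
        probability of reaching it.  ``exclude_after`` zeroes the energy
        of members downstream of the named nuclide — a bounding
        sensitivity for daughter (recoil) redistribution.
        """
        total = 0.0
        excluded: set[str] = set()
        if exclude_after is not None:
            frontier = {exclude_after}
            while frontier:
                nxt = {s.child for s in self.steps
                       if s.parent in frontier} - excluded
                excluded |= nxt
                frontier = nxt
        for name in self.members:
            if name in excluded:
                continue
            nuc = self.nuclides[name]
            if nuc.decay_constant == 0.0:
                continue  # stable end of chain
            total += self.path_probability(name) * nuc.local_energy_mev
        return total


def load_nuclide_table(path: str | Path) -> tuple[dict[str, Nuclide], dict[str, DecayChain]]:
    """Load nuclide constants and decay chains from the YAML data file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    nuclides = {
        name: Nuclide(name=name,
                      half_life_days=float(entry["half_life_days"]),
                      alpha_mev=float(entry.get("alpha_mev", 0.0)),
                      electron_mev=float(entry.get("electron_mev", 0.0)))
        for name, entry in raw["nuclides"].items()
    }
    chains = {}
    for parent, steps in raw.get("chains", {}).items():
        chain_steps = [ChainStep(s["parent"], s["child"], float(s["fraction"]))
                       for s in steps]
        chains[parent] = DecayChain(parent=parent, nuclides=nuclides,
                                    steps=chain_steps)
    return nuclides, chains


# ---------------------------------------------------------------------------
# Bateman chain activities
# ---------------------------------------------------------------------------

def _bateman_number(lambdas: np.ndarray, t: float, n1_0: float) -> float:
    """Number of atoms of the last member of a linear chain at time t.

    Classical Bateman solution with all daughters starting at zero.  The
    last decay constant may be zero (stable accumulation).  Decay
    constants must be pairwise distinct.
    """
    n = len(lambdas)
    if n == 1:
        return n1_0 * float(np.exp(-lambdas[0] * t))
    coeff = n1_0 * float(np.prod(lambdas[:-1]))
    total = 0.0
    for i in range(n):
        denom = 1.0
        for j in range(n):
            if j != i:
                denom *= lambdas[j] - lambdas[i]
        # exp underflow for very short-lived members is the correct limit
        with np.errstate(over="ignore"):
            term = np.exp(-lambdas[i] * t) / denom
        total += float(term)
    return coeff * total


def bateman_numbers(chain: DecayChain, t: float,
                    parent_activity_at_0: float = 1.0) -> dict[str, float]:
    """Per-member atom numbers at time ``t`` (days) for a chain whose
    parent starts at ``parent_activity_at_0`` Bq with all daughters absent.

    Branch paths are summed with their branching-fraction products, so
    converging branches (e.g. two routes into the same granddaughter)
    are handled.  Stable end members accumulate (decay constant zero).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    lam_parent = chain.nuclides[chain.parent].decay_constant
    if lam_parent == 0:
        raise ValueError("chain parent must be radioactive")
    n1_0 = parent_activity_at_0 / lam_parent
    if t == 0:  # exact initial condition, avoids cancellation residue
        return {m: (n1_0 if m == chain.parent else 0.0)
                for m in chain.members}
    out: dict[str, float] = {}
    for member in chain.members:
        number = 0.0
        for path in chain.paths_to(member):
            lambdas = np.array(
                [lam_parent] + [chain.nuclides[s.child].decay_constant
                                for s in path]
            )
            if len(np.unique(lambdas)) != len(lambdas):
                raise ValueError("degenerate (equal) decay constants in path")
            branch = float(np.prod([s.fraction for s in path]) if path else 1.0)
            number += branch * _bateman_number(lambdas, t, n1_0)
        out[member] = number
    return out


def bateman_activity(chain: DecayChain, t: float,
                     parent_activity_at_0: float = 1.0) -> dict[str, float]:
    """Per-member activities (Bq) at time ``t`` (days); see
    :func:`bateman_numbers` for the underlying atom balance."""
    numbers = bateman_numbers(chain, t, parent_activity_at_0)
    return {m: chain.nuclides[m].decay_constant * numbers[m]
            for m in chain.members}


def equilibrium_ratio(chain: DecayChain, member: str, t: float) -> float:
    """Activity ratio member/parent at time ``t`` — the secular-equilibrium
    check used before surrogate-daughter counting."""
    act = bateman_activity(chain, t, parent_activity_at_0=1.0)
    return act[member] / act[chain.parent]


# ---------------------------------------------------------------------------
# %IA/g and group statistics
# ---------------------------------------------------------------------------

@dataclass
class BiodistSample:
    organ: str
    mass_g: float
    cpm: float
    dt_days: float = 0.0     # counting delay relative to the standard
    group: str = ""
    animal: str = ""

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("sample mass must be positive")
        if self.cpm < 0:
            raise ValueError("counts must be non-negative")


def percent_ia_per_gram(sample: BiodistSample, standard_cpm: float,
                        nuclide: Nuclide,
                        standard_fraction: float = 1.0) -> float:
    """Percent injected activity per gram of tissue.

    ``standard_cpm`` is the count rate of a reference standard at its own
    counting time representing ``standard_fraction`` of the injected
    activity.  Sample counts are decay-corrected to the standard's
    reference time by ``exp(+lambda * dt)`` before normalization.
    """
    if standard_cpm <= 0:
        raise ValueError("standard counts must be positive")
    if not 0 < standard_fraction <= 1:
        raise ValueError("standard_fraction must lie in (0, 1]")
    corrected = sample.cpm * np.exp(nuclide.decay_constant * sample.dt_days)
    injected_cpm = standard_cpm / standard_fraction
    return float(100.0 * corrected / (injected_cpm * sample.mass_g))


def holm_sidak(p_raw: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjustment.

    Sorted ascending, ``p_adj(i) = 1 - (1 - p(i))^(m - i + 1)`` with the
    sequence forced monotone non-decreasing.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    with np.errstate(divide="ignore"):  # p = 1 is a legal input
        return multipletests(p_raw, method="holm-sidak")[1]


def compare_groups(values: pd.DataFrame, group_a: str, group_b: str,
                   value_col: str = "pct_ia_per_g",
                   organ_col: str = "organ",
                   group_col: str = "group") -> pd.DataFrame:
    """Per-organ Welch t-tests between two groups with Holm-Sidak
    adjustment across organs.

    ``values`` is long-form with one row per animal x organ.  Returns a
    DataFrame with raw and adjusted p-values and group means +- sd.
    """
    rows = []
    for organ, sub in values.groupby(organ_col, sort=True):
        a = sub.loc[sub[group_col] == group_a, value_col].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == group_b, value_col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"organ {organ!r}: need >= 2 values per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({
            "organ": organ,
            f"mean_{group_a}": a.mean(), f"sd_{group_a}": a.std(ddof=1),
            f"mean_{group_b}": b.mean(), f"sd_{group_b}": b.std(ddof=1),
            "p_raw": p,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_sidak(out["p_raw"].to_numpy())
    return out


__all__ = [
    "BiodistSample",
    "ChainStep",
    "DecayChain",
    "Nuclide",
    "bateman_activity",
    "bateman_numbers",
    "compare_groups",
    "equilibrium_ratio",
    "holm_sidak",
    "load_nuclide_table",
    "percent_ia_per_gram",
]
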