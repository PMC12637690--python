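"""Seeded synthetic scRNA-seq generators.

Counts are drawn from a gamma-Poisson (negative-binomial) model: each cell
gets a group, a lognormal library size, and per-gene means equal to the
library size times the group's normalized mean expression profile, with a
shared inverse-dispersion.  Two experiment shapes are provided:

* a *spike-in* design — a dominant base population mixed with rare
  heterogeneous populations at controlled fractions, emulating graded
  imbalance of an atlas spiked into a single-tissue corpus;
* a *perturbation* design — paired control/perturbed populations across
  several cell groups, where the perturbation multiplies expression by
  ``exp(shared_shift * group_modulation)`` (an additive shift per group in
  log-expression space).

Group mean profiles default to a shared lognormal baseline with a sparse
set of group-specific up-regulated genes, giving controllable separation.
Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import CellMatrix

DEFAULT_SPIKE_FRACTIONS = (0.0, 1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.5)


@dataclass
class SyntheticSpec:
    """Generative description of one synthetic dataset.

    ``groups`` is a list of ``{"name", "proportion", "mean_profile"}``
    dicts; proportions must sum to 1 and profiles must be positive.
    ``dispersion`` is the NB inverse-dispersion (np.inf selects the Poisson
    limit).  ``perturbation``, when present, is
    ``{"shared_shift": length-D log-fold-change vector,
    "group_modulation": {group: positive scalar}}``.
    """

    n_genes: int
    groups: list
    n_cells: int = 1000
    dispersion: float = 2.0
    library_size_lognormal: tuple = (np.log(2500.0), 0.35)
    perturbation: dict | None = None
    seed: int = 0

    def __post_init__(self):
        props = np.array([g["proportion"] for g in self.groups], dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {props.sum()}, not 1")
        if not (self.dispersion > 0):
            raise ValueError("dispersion must be positive")
        for g in self.groups:
            prof = np.asarray(g["mean_profile"], dtype=float)
            if prof.shape[0] != self.n_genes:
                raise ValueError(f"group {g['name']}: profile length != n_genes")
            if np.all(prof == 0):
                raise ValueError(f"group {g['name']}: degenerate all-zero profile")
            if np.any(prof < 0):
                raise ValueError(f"group {g['name']}: negative profile entries")
            g["mean_profile"] = prof
        if self.perturbation is not None:
            shift = np.asarray(self.perturbation["shared_shift"], dtype=float)
            if shift.shape[0] != self.n_genes:
                raise ValueError("shared_shift length != n_genes")
            self.perturbation["shared_shift"] = shift
            for name, m in self.perturbation["group_modulation"].items():
                if not m > 0:
                    raise ValueError(f"group_modulation for {name!r} must be > 0")

    def to_json(self) -> str:
        d = {
            "n_genes": self.n_genes, "n_cells": self.n_cells,
            "dispersion": None if np.isinf(self.dispersion) else self.dispersion,
            "library_size_lognormal": list(self.library_size_lognormal),
            "seed": self.seed,
            "groups": [{"name": g["name"], "proportion": g["proportion"],
                        "mean_profile": np.asarray(g["mean_profile"]).tolist()}
                       for g in self.groups],
        }
        if self.perturbation is not None:
            d["perturbation"] = {
                "shared_shift": self.perturbation["shared_shift"].tolist(),
                "group_modulation": dict(self.perturbation["group_modulation"]),
            }
        return json.dumps(d)


@dataclass
class MixtureDesign:
    """Spike-in layout: a base population plus graded rare fractions."""

    total_n: int
    base_group: str
    spike_fractions: tuple = DEFAULT_SPIKE_FRACTIONS

    def __post_init__(self):
        if self.total_n < 1:
            raise ValueError("total_n must be >= 1")
        for f in self.spike_fractions:
            if not 0.0 <= f <= 0.5:
                raise ValueError(f"spike fraction {f} outside [0, 0.5]")


def make_group_profiles(
    n_genes: int,
    group_names,
    baseline_sigma: float = 1.0,
    frac_up: float = 0.05,
    fold: float = 4.0,
    seed: int = 0,
) -> list:
    """Shared lognormal gene baseline plus, per group, ``frac_up`` of genes
    up-regulated ``fold``-times — disjoint marker sets per group."""
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n_genes)
    names = list(group_names)
    n_up = max(1, int(round(frac_up * n_genes)))
    markers = rng.permutation(n_genes)[: n_up * len(names)]
    profiles = []
    for i, name in enumerate(names):
        prof = baseline.copy()
        prof[markers[i * n_up:(i + 1) * n_up]] *= fold
        profiles.append({"name": name, "mean_profile": prof})
    return profiles


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _simulate_given_groups(spec: SyntheticSpec, group_assignment: np.ndarray,
                           rng: np.random.Generator,
                           condition: np.ndarray | None = None) -> CellMatrix:
    n = len(group_assignment)
    by_name = {g["name"]: np.asarray(g["mean_profile"], dtype=float) for g in spec.groups}
    mu_lib, sigma_lib = spec.library_size_lognormal
    lib = rng.lognormal(mean=mu_lib, sigma=sigma_lib, size=n)
    X = np.empty((n, spec.n_genes))
    for i in range(n):
        prof = by_name[group_assignment[i]]
        if condition is not None and condition[i] == "perturbed":
            pert = spec.perturbation
            prof = prof * np.exp(pert["shared_shift"]
                                 * pert["group_modulation"][group_assignment[i]])
        p = prof / prof.sum()
        X[i] = _nb_counts(rng, lib[i] * p, spec.dispersion)
    return CellMatrix(X=X, group=group_assignment, condition=condition)


def simulate_counts(spec: SyntheticSpec, n_cells: int | None = None) -> CellMatrix:
    """Draw an imbalanced multi-group count matrix from the spec."""
    n = spec.n_cells if n_cells is None else n_cells
    rng = np.random.default_rng(spec.seed)
    props = np.array([g["proportion"] for g in spec.groups], dtype=float)
    names = np.array([g["name"] for g in spec.groups], dtype=object)
    assignment = rng.choice(names, size=n, p=props / props.sum())
    return _simulate_given_groups(spec, assignment.astype(str), rng)


def build_spikein(design: MixtureDesign, spec: SyntheticSpec) -> dict:
    """One dataset per spike fraction.

    For fraction f, ``round(f * total_n)`` cells are drawn uniformly from
    the non-base groups and the remainder from the base group; a positive
    fraction that rounds to zero cells is bumped to a single cell (the
    rarest arm of the design keeps exactly one spiked cell).  Returns
    ``{fraction: CellMatrix}``.
    """
    non_base = [g["name"] for g in spec.groups if g["name"] != design.base_group]
    if design.base_group not in {g["name"] for g in spec.groups}:
        raise ValueError(f"base group {design.base_group!r} not in spec")
    if not non_base:
        raise ValueError("spike-in design needs at least one non-base group")
    out = {}
    for j, f in enumerate(design.spike_fractions):
        n_spike = int(round(f * design.total_n))
        if f > 0 and n_spike < 1:
            warnings.warn(f"fraction {f} yields <1 cell at total_n={design.total_n}; using 1")
            n_spike = 1
        rng = np.random.default_rng([spec.seed, j])
        spiked = rng.choice(np.array(non_base, dtype=object), size=n_spike)
        assignment = np.concatenate([
            np.full(design.total_n - n_spike, design.base_group, dtype=object), spiked])
        assignment = rng.permutation(assignment)
        out[f] = _simulate_given_groups(spec, assignment.astype(str), rng)
    return out


def simulate_perturbation(spec: SyntheticSpec, n_cells: int | None = None) -> CellMatrix:
    """Paired control/perturbed counts across groups.

    Every group emits both conditions (50/50 within the group's draw);
    perturbed cells use the group's profile times
    ``exp(shared_shift * group_modulation)``.
    """
    if spec.perturbation is None:
        raise ValueError("spec has no perturbation field")
    n = spec.n_cells if n_cells is None else n_cells
    rng = np.random.default_rng(spec.seed)
    props = np.array([g["proportion"] for g in spec.groups], dtype=float)
    names = np.array([g["name"] for g in spec.groups], dtype=object)
    assignment = rng.choice(names, size=n, p=props / props.sum()).astype(str)
    condition = np.where(rng.random(n) < 0.5, "control", "perturbed").astype(object)
    return _simulate_given_groups(spec, assignment, rng, condition=condition.astype(str))


def simulate_latent_shift(
    n_cells: int = 3000,
    n_genes: int = 100,
    k_latent: int = 5,
    n_groups: int = 3,
    shift_norm: float = 3.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> CellMatrix:
    """Linear-Gaussian data whose perturbation is an exact additive shift in
    the generative latent space.

    Cells live at ``z ~ N(center_g, I)`` in ``k_latent`` dimensions;
    perturbed cells are shifted by a fixed vector of norm ``shift_norm``;
    expression is a linear map to ``n_genes`` plus Gaussian noise.  Because
    the map is linear, the perturbation is also exactly additive in gene
    space — the ground truth for latent-arithmetic recovery tests.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 2.0, size=(n_groups, k_latent))
    g = rng.integers(n_groups, size=n_cells)
    cond = np.where(rng.random(n_cells) < 0.5, "control", "perturbed")
    Z = centers[g] + rng.normal(size=(n_cells, k_latent))
    shift = rng.normal(size=k_latent)
    shift *= shift_norm / np.linalg.norm(shift)
    Z[cond == "perturbed"] += shift
    W = rng.normal(size=(k_latent, n_genes)) / np.sqrt(k_latent)
    X = Z @ W + noise_sd * rng.normal(size=(n_cells, n_genes))
    return CellMatrix(X=X, group=np.array([f"g{i}" for i in g]),
                      condition=cond.astype(str))


def default_spikein_spec(n_genes: int = 200, n_rare_groups: int = 3,
                         seed: int = 0) -> tuple[SyntheticSpec, MixtureDesign]:
    """Desk-scale default spike-in setup: one base group plus
    ``n_rare_groups`` heterogeneous spike groups."""
    names = ["base"] + [f"rare{i}" for i in range(n_rare_groups)]
    profiles = make_group_profiles(n_genes, names, seed=seed)
    for g in profiles:
        g["proportion"] = 1.0 / len(names)  # placeholder; spike-in fixes counts
    spec = SyntheticSpec(n_genes=n_genes, groups=profiles, seed=seed)
    design = MixtureDesign(total_n=5000, base_group="base")
    return spec, design


def default_perturbation_spec(n_genes: int = 200, n_groups: int = 3,
                              n_cells: int = 3000, shift_frac: float = 0.1,
                              shift_logfc: float = np.log(4.0),
                              seed: int = 0) -> SyntheticSpec:
    """Desk-scale perturbation setup: ``n_groups`` equally sized groups, a
    shared sparse log-fold-change response, mild per-group modulation."""
    names = [f"group{i}" for i in range(n_groups)]
    profiles = make_group_profiles(n_genes, names, seed=seed)
    for g in profiles:
        g["proportion"] = 1.0 / n_groups
    rng = np.random.default_rng([seed, 7])
    shift = np.zeros(n_genes)
    responsive = rng.permutation(n_genes)[: max(1, int(round(shift_frac * n_genes)))]
    shift[responsive] = shift_logfc * rng.choice([-1.0, 1.0], size=len(responsive))
    modulation = {name: 1.0 + 0.2 * i for i, name in enumerate(names)}
    return SyntheticSpec(
        n_genes=n_genes, groups=profiles, n_cells=n_cells,
        perturbation={"shared_shift": shift, "group_modulation": modulation},
        seed=seed,
    )
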