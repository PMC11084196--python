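"""Seeded generators for ligand tables, binding sites and sensorgrams.

Every downstream stage of the screen is testable without database access:

* :func:`gen_ligand_table` emulates a DrugBank-like candidate table. Each
  filterable attribute is sampled independently, and the probability of
  passing each filter is controlled exactly by first drawing a pass/fail
  Bernoulli at the configured fraction and then sampling the attribute from
  its marginal restricted to the pass (or fail) region -- so expected
  survivor counts per single filter are analytic. Marginals: mass uniform
  on [50, 1200] Da (both tails of the mass window exercised), solubility
  and plasma concentration log-uniform, BBB penetration uniform on [0, 100].
* :func:`gen_binding_sites` plants cluster archetypes in distinct regions
  of the HSA chain (defaults anchored at residues 447, 452, 117, 145, 292,
  the hallmark residues of the five empirically observed site clusters) and
  jitters member sites by removing/adding residues. The planted label is
  stored on each site for recovery tests; clustering never reads it.
* :func:`gen_sensorgram` adds pointwise Gaussian noise to the closed-form
  two-site sensorgram, so the zero-noise output is bit-identical to
  :func:`hsascreen.spr.simulate_sensorgram`.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from hsascreen.clustering import N_HSA_RESIDUES, BindingSite
from hsascreen.ligand_filter import STAGE_NAMES, FilterThresholds, LigandRecord
from hsascreen.spr import KineticParams, Sensorgram, simulate_sensorgram

__all__ = [
    "GeneratorConfig",
    "DEFAULT_ARCHETYPE_ANCHORS",
    "gen_ligand_table",
    "gen_binding_sites",
    "gen_sensorgram",
    "write_binding_sites_json",
    "read_binding_sites_json",
]

#: Anchor residues for the default five archetypes, one per known site
#: cluster region on HSA (subdomain IIA/IIB boundary, IIIA, IB, the IB
#: cleft, and IIA).
DEFAULT_ARCHETYPE_ANCHORS: tuple[int, ...] = (447, 452, 117, 145, 292)

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _aa_for_residue(number: int) -> str:
    """Deterministic amino-acid code for a synthetic residue number.

    The screen's distance ignores the code; a fixed pseudo-sequence keeps
    generated sites byte-stable across calls.
    """
    return _AA_ALPHABET[(number * 7) % len(_AA_ALPHABET)]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    ``filter_pass_fractions`` gives, per filter stage, the marginal
    probability that a generated ligand passes that single filter.
    Defaults mimic a plausible attrition profile of a repurposing screen.
    ``analyte_concs`` defaults to the five-point HSA titration (2.5-40 uM)
    used in the SPR assay.
    """

    seed: int = 0
    n_ligands: int = 100
    filter_pass_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "mass": 0.7,
            "solubility": 0.8,
            "bbb": 0.5,
            "plasma": 0.6,
            "refs": 0.4,
            "fatty_acid": 0.9,
        }
    )
    n_clusters: int = 5
    sites_per_cluster: int = 10
    archetype_size: int = 8
    site_jitter: int = 1
    archetype_anchors: tuple[int, ...] = DEFAULT_ARCHETYPE_ANCHORS
    noise_sd: float = 1.0  # RU
    analyte_concs: tuple[float, ...] = (2.5e-6, 5e-6, 10e-6, 20e-6, 40e-6)

    def __post_init__(self) -> None:
        if self.n_ligands < 0 or self.n_clusters < 0 or self.sites_per_cluster < 0:
            raise ValueError("counts must be >= 0")
        unknown = set(self.filter_pass_fractions) - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown filter names: {sorted(unknown)}")
        for name, frac in self.filter_pass_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"pass fraction for {name!r} not in [0, 1]: {frac}")
        if self.site_jitter < 0 or self.site_jitter > self.archetype_size:
            raise ValueError("site_jitter must be in [0, archetype_size]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _uniform_two_sided(
    rng: np.random.Generator, lo: float, a: float, b: float, hi: float
) -> float:
    """Uniform draw from [lo, a] union [b, hi], weighted by segment width."""
    w1, w2 = a - lo, hi - b
    if rng.uniform(0, w1 + w2) < w1:
        return float(rng.uniform(lo, a))
    return float(rng.uniform(b, hi))


def gen_ligand_table(
    cfg: GeneratorConfig, thr: FilterThresholds | None = None
) -> list[LigandRecord]:
    """Generate ``cfg.n_ligands`` records with controlled per-filter pass rates.

    Attributes are sampled independently; for each filter the pass
    indicator is Bernoulli(cfg.filter_pass_fractions[name]) and the
    attribute value is then drawn from the marginal restricted to the
    corresponding side of the threshold in ``thr``.
    """
    thr = thr if thr is not None else FilterThresholds()
    rng = np.random.default_rng(cfg.seed)
    frac = cfg.filter_pass_fractions
    records = []
    for i in range(cfg.n_ligands):
        # mass: uniform on [50, 1200] Da, window (mass_min, mass_max)
        if rng.random() < frac.get("mass", 0.5):
            mass = float(rng.uniform(thr.mass_min + 1e-9, thr.mass_max))
        else:
            mass = _uniform_two_sided(rng, 50.0, thr.mass_min, thr.mass_max, 1200.0)
        # solubility: log-uniform over [1e-3, 1e4] uM
        if rng.random() < frac.get("solubility", 0.5):
            solubility = _loguniform(rng, max(thr.solubility_min, 1e-6) * (1 + 1e-9), 1e4)
        else:
            solubility = _loguniform(rng, 1e-3, max(thr.solubility_min, 1e-3))
        # BBB: uniform percent
        if rng.random() < frac.get("bbb", 0.5):
            bbb = float(rng.uniform(thr.bbb_min + 1e-9, 100.0))
        else:
            bbb = float(rng.uniform(0.0, thr.bbb_min))
        # plasma concentration: log-uniform over [1e-4, 1e4] nM
        if rng.random() < frac.get("plasma", 0.5):
            plasma = _loguniform(rng, max(thr.plasma_min, 1e-6) * (1 + 1e-9), 1e4)
        else:
            plasma = _loguniform(rng, 1e-4, max(thr.plasma_min, 1e-4))
        # literature references: passing compounds get refs_min + Poisson(4)
        if rng.random() < frac.get("refs", 0.5):
            refs = int(thr.refs_min + rng.poisson(4))
        else:
            refs = int(rng.integers(0, thr.refs_min))
        is_fa = rng.random() >= frac.get("fatty_acid", 1.0)
        records.append(
            LigandRecord(
                id=f"SYN{i:05d}",
                name=f"synthetic-ligand-{i}",
                mass=mass,
                solubility=solubility,
                bbb_penetration=bbb,
                plasma_conc=plasma,
                ad_refs=refs,
                is_fatty_acid=bool(is_fa),
            )
        )
    return records


def _make_archetype(
    rng: np.random.Generator, anchor: int, size: int, spread: int = 12
) -> list[int]:
    """Distinct residue numbers near an anchor position on the chain."""
    lo = max(1, anchor - spread)
    hi = min(N_HSA_RESIDUES, anchor + spread)
    pool = np.arange(lo, hi + 1)
    if size > pool.size:
        raise ValueError(f"archetype size {size} exceeds window around {anchor}")
    chosen = rng.choice(pool, size=size, replace=False)
    return sorted(int(r) for r in chosen)


def gen_binding_sites(cfg: GeneratorConfig) -> list[BindingSite]:
    """Binding sites with planted cluster structure.

    For each of ``cfg.n_clusters`` archetypes, ``cfg.sites_per_cluster``
    member sites are produced by removing ``site_jitter`` random residues
    from the archetype and adding ``site_jitter`` fresh residues from the
    archetype's neighbourhood. Each site records its planted label in
    ``true_cluster``.
    """
    if cfg.n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if cfg.n_clusters > len(cfg.archetype_anchors):
        raise ValueError(
            f"n_clusters={cfg.n_clusters} exceeds available anchors "
            f"({len(cfg.archetype_anchors)})"
        )
    rng = np.random.default_rng(cfg.seed)
    sites: list[BindingSite] = []
    for c in range(cfg.n_clusters):
        anchor = cfg.archetype_anchors[c]
        archetype = _make_archetype(rng, anchor, cfg.archetype_size)
        window_lo = max(1, anchor - 12)
        window_hi = min(N_HSA_RESIDUES, anchor + 12)
        for m in range(cfg.sites_per_cluster):
            residues = list(archetype)
            if cfg.site_jitter > 0:
                drop = rng.choice(
                    len(residues), size=cfg.site_jitter, replace=False
                )
                residues = [r for i, r in enumerate(residues) if i not in set(drop.tolist())]
                candidates = [
                    r
                    for r in range(window_lo, window_hi + 1)
                    if r not in residues
                ]
                add = rng.choice(len(candidates), size=cfg.site_jitter, replace=False)
                residues += [candidates[i] for i in add.tolist()]
            residues = sorted(residues)
            sites.append(
                BindingSite(
                    ligand_id=f"SYN{c:02d}-{m:03d}",
                    residues=tuple((r, _aa_for_residue(r)) for r in residues),
                    true_cluster=c + 1,
                )
            )
    return sites


def gen_sensorgram(
    kp: KineticParams,
    rmax1: float,
    rmax2: float,
    conc: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 2400.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sensorgram:
    """Noisy two-site sensorgram on a uniform grid.

    Defaults mirror the SPR protocol: 300 s association, 2400 s
    dissociation. The zero-noise trace equals
    :func:`hsascreen.spr.simulate_sensorgram` exactly.
    """
    if t_assoc <= 0 or t_dissoc <= 0 or dt <= 0:
        raise ValueError("t_assoc, t_dissoc and dt must be > 0")
    if conc < 0:
        raise ValueError("analyte concentration must be >= 0")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    sg = simulate_sensorgram(kp, rmax1, rmax2, conc, times, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sg.response = sg.response + rng.normal(0.0, noise_sd, size=times.size)
    return sg


def write_binding_sites_json(sites: Sequence[BindingSite], path: str | Path) -> None:
    payload = []
    for s in sites:
        entry = {
            "ligand_id": s.ligand_id,
            "residues": [{"number": n, "aa": aa} for n, aa in s.residues],
        }
        if s.true_cluster is not None:
            entry["true_cluster"] = s.true_cluster
        payload.append(entry)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_binding_sites_json(path: str | Path) -> list[BindingSite]:
    payload = json.loads(Path(path).read_text())
    return [
        BindingSite(
            ligand_id=e["ligand_id"],
            residues=tuple((int(r["number"]), r["aa"]) for r in e["residues"]),
            true_cluster=e.get("true_cluster"),
        )
        for e in payload
    ]
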