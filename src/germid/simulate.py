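"""Synthetic genebank panels with planted ground truth.

The generator emulates the statistical structure a clonal-collection
integrity analysis has to cope with: several species populations
diverged from a shared ancestral allele pool (Balding-Nichols model),
inter-specific F1 hybrids, clonal duplicate groups whose members differ
only by genotyping error, a replicated internal-control clone,
homonymous names, planted species mislabels, and sporadic missing
calls.  Every planted feature is recorded in a :class:`SimTruth` so
recovery can be scored exactly.

Default magnitudes are the study conditions of a realistic single-dose
SNP panel: 357 loci, ancestral minor-allele frequencies from a
Beta(2, 11) restricted to [0.05, 0.5] (mean about 0.153), per-call
error rate 9.3e-4, missing rate 1.5e-3, and six species populations
whose Balding-Nichols parameters span pairwise differentiation of
roughly 0.07-0.32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PassportTable, write_genotype_csv

__all__ = [
    "SpeciesSpec",
    "CloneGroupPlan",
    "SimConfig",
    "SimTruth",
    "simulate_frequencies",
    "simulate_panel",
    "write_fixture",
]


@dataclass
class SpeciesSpec:
    name: str
    n: int
    fst: float  # Balding-Nichols divergence from the ancestral pool


def default_species() -> list:
    # sample sizes follow the core-member census of a large Saccharum
    # collection; divergence parameters span pairwise F_ST ~ 0.07-0.32
    return [
        SpeciesSpec("S. barberi", 19, 0.15),
        SpeciesSpec("S. robustum", 62, 0.26),
        SpeciesSpec("S. officinarum", 104, 0.08),
        SpeciesSpec("S. sinense", 28, 0.32),
        SpeciesSpec("S. spontaneum SE Asia", 99, 0.20),
        SpeciesSpec("S. spontaneum India", 100, 0.22),
    ]


@dataclass
class CloneGroupPlan:
    n_groups: int = 10
    min_size: int = 2
    max_size: int = 5


@dataclass
class SimConfig:
    seed: int
    n_loci: int = 357
    maf_beta: tuple = (2.0, 11.0)
    maf_range: tuple = (0.05, 0.5)
    species: list = field(default_factory=default_species)
    clone_groups: CloneGroupPlan = field(default_factory=CloneGroupPlan)
    error_rate: float = 0.00093
    missing_rate: float = 0.0015
    n_mislabels: int = 8
    n_homonyms: int = 5
    n_hybrids: int = 10
    n_replicates: int = 12

    def __post_init__(self):
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.species = [
            s if isinstance(s, SpeciesSpec) else SpeciesSpec(**s) for s in self.species
        ]
        if isinstance(self.clone_groups, dict):
            self.clone_groups = CloneGroupPlan(**self.clone_groups)


@dataclass
class SimTruth:
    """Ground truth for every planted feature of a synthetic panel."""

    true_species: dict                 # code -> species name (or 'hybrid')
    clone_groups: list                 # list of member-code lists (incl. controls)
    replicate_group: list              # codes of the internal-control set
    error_loci: dict                   # code -> list of perturbed locus ids
    mislabels: dict                    # code -> {"recorded": ..., "true": ...}
    homonyms: dict                     # shared name -> list of codes
    hybrid_parents: dict               # code -> [parent species, parent species]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _ancestral_frequencies(cfg: SimConfig, rng) -> np.ndarray:
    a, b = cfg.maf_beta
    lo, hi = cfg.maf_range
    maf = np.empty(cfg.n_loci)
    filled = 0
    while filled < cfg.n_loci:
        draw = rng.beta(a, b, size=2 * cfg.n_loci)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), cfg.n_loci - filled)
        maf[filled : filled + take] = draw[:take]
        filled += take
    flip = rng.random(cfg.n_loci) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def simulate_frequencies(cfg: SimConfig, rng=None):
    """Ancestral and per-species allele frequencies (Balding-Nichols).

    Species frequencies are Beta(p (1-F)/F, (1-p) (1-F)/F) around the
    ancestral frequency p, so the expected differentiation of a species
    from the ancestral pool equals its configured F.  ``F = 0`` is the
    no-divergence shortcut.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = _ancestral_frequencies(cfg, rng)
    by_species = {}
    for spec in cfg.species:
        if spec.fst == 0.0:
            by_species[spec.name] = p.copy()
            continue
        if not 0.0 < spec.fst < 1.0:
            raise ValueError(f"F_ST for {spec.name} outside (0, 1): {spec.fst}")
        scale = (1.0 - spec.fst) / spec.fst
        by_species[spec.name] = rng.beta(p * scale, (1.0 - p) * scale)
    return p, by_species


def _perturb(calls, rng, error_rate):
    """Independently flip each call to one of the other two codes."""
    hit = rng.random(calls.shape) < error_rate
    shift = rng.integers(1, 3, size=calls.shape)
    return np.where(hit, (calls + shift) % 3, calls).astype(np.int8), hit


def simulate_panel(cfg: SimConfig):
    """Generate a full synthetic genebank panel.

    Returns ``(GenotypeMatrix, PassportTable, SimTruth)``.  Species
    individuals are Hardy-Weinberg draws from their species frequencies;
    hybrids are F1 gamete mixes of two species; clone-group members and
    the replicate-control set copy a progenitor genotype with per-call
    error; homonyms, mislabels and missing data are planted last.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestral, freqs = simulate_frequencies(cfg, rng)
    locus_ids = [f"L{j:04d}" for j in range(cfg.n_loci)]

    calls_rows, codes, names, species_rec, species_true = [], [], [], [], []
    origins, rep_group = [], []
    truth = SimTruth({}, [], [], {}, {}, {}, {})
    counter = 0
    regions = ["India", "Indonesia", "Papua New Guinea", "Hawaii", "Barbados",
               "China", "Unknown"]

    def new_code():
        nonlocal counter
        counter += 1
        return f"SAC{counter:04d}"

    def add(genotype, name, rec_species, true_species, rep=None):
        code = new_code()
        calls_rows.append(genotype)
        codes.append(code)
        names.append(name)
        species_rec.append(rec_species)
        species_true.append(true_species)
        origins.append(regions[int(rng.integers(len(regions)))])
        rep_group.append(rep)
        truth.true_species[code] = true_species
        return code

    # --- species populations ---
    for spec in cfg.species:
        p = freqs[spec.name]
        draws = rng.binomial(2, p, size=(spec.n, cfg.n_loci)).astype(np.int8)
        for i in range(spec.n):
            add(draws[i], f"{spec.name.split()[-1].upper()}-{i:03d}",
                spec.name, spec.name)

    # --- F1 hybrids between successive species pairs ---
    for h in range(cfg.n_hybrids):
        a = cfg.species[h % len(cfg.species)]
        b = cfg.species[(h + 1) % len(cfg.species)]
        gam_a = rng.binomial(1, freqs[a.name])
        gam_b = rng.binomial(1, freqs[b.name])
        code = add((gam_a + gam_b).astype(np.int8), f"HYB-{h:03d}", "hybrid", "hybrid")
        truth.hybrid_parents[code] = [a.name, b.name]

    n_base = len(codes)

    # --- clone duplicate groups (synonyms) ---
    plan = cfg.clone_groups
    n_species_inds = n_base - cfg.n_hybrids
    progenitors = (
        rng.choice(n_species_inds, size=plan.n_groups + 1, replace=False)
        if plan.n_groups + 1 <= n_species_inds
        else list(range(n_species_inds))
    )
    if plan.n_groups > 0:
        for g, prog in enumerate(progenitors[:-1]):
            size = int(rng.integers(plan.min_size, plan.max_size + 1))
            members = [codes[prog]]
            for m in range(size - 1):
                copy, hit = _perturb(calls_rows[prog], rng, cfg.error_rate)
                code = add(copy, f"SYN-{g:02d}-{m}", species_rec[prog],
                           species_true[prog])
                truth.error_loci[code] = [locus_ids[j] for j in np.flatnonzero(hit)]
            members += codes[-(size - 1):] if size > 1 else []
            truth.clone_groups.append(members)

    # --- replicated internal control (progenitor distinct from clone groups) ---
    prog = int(progenitors[-1])
    control = []
    for m in range(cfg.n_replicates):
        copy, hit = _perturb(calls_rows[prog], rng, cfg.error_rate)
        code = add(copy, "P-CTRL-01", species_rec[prog], species_true[prog],
                   rep="CTRL")
        truth.error_loci[code] = [locus_ids[j] for j in np.flatnonzero(hit)]
        control.append(code)
    truth.replicate_group = control
    # the progenitor individual remains in the panel and is genotypically
    # part of the same clonal lineage
    truth.clone_groups.append([codes[prog]] + control)

    # --- homonyms: one name shared by unrelated clones ---
    base_idx = rng.choice(n_base, size=2 * cfg.n_homonyms, replace=False)
    for h in range(cfg.n_homonyms):
        i, j = int(base_idx[2 * h]), int(base_idx[2 * h + 1])
        shared = f"HOMONYM-{h:02d}"
        names[i] = names[j] = shared
        truth.homonyms[shared] = [codes[i], codes[j]]

    # --- planted species mislabels ---
    eligible = [
        i for i in range(n_base)
        if species_true[i] != "hybrid" and rep_group[i] is None
    ]
    for i in rng.choice(eligible, size=cfg.n_mislabels, replace=False):
        others = [s.name for s in cfg.species if s.name != species_true[i]]
        wrong = others[int(rng.integers(len(others)))]
        truth.mislabels[codes[i]] = {"recorded": wrong, "true": species_true[i]}
        species_rec[i] = wrong

    calls = np.vstack(calls_rows)
    missing = rng.random(calls.shape) < cfg.missing_rate
    gm = GenotypeMatrix(codes, locus_ids, calls, missing)
    passport = PassportTable(
        pd.DataFrame(
            {
                "clone_code": codes,
                "clone_name": names,
                "recorded_species": species_rec,
                "origin": origins,
                "replicate_group": rep_group,
            }
        )
    )
    return gm, passport, truth


def write_fixture(bundle, outdir) -> None:
    """Write ``(genotypes, passport, truth)`` as CSV + CSV + JSON.

    Output is byte-for-byte determined by the generating seed.
    """
    import pathlib

    gm, passport, truth = bundle
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_csv(gm, outdir / "genotypes.csv")
    passport.table.reset_index(drop=True).to_csv(outdir / "passport.csv", index=False)
    truth.to_json(outdir / "truth.json")
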