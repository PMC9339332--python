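"""DO-style synthetic studies: founder mosaics, SNP tables, planted traits.

Haplotype mosaics follow a first-order Markov chain along each chromosome:
between adjacent markers separated by d cM, a recombination event occurs
with probability ``1 - exp(-g * d / 100)`` (``g`` scales with outbreeding
generations) and the new founder is drawn uniformly from the 8.  Founder
equilibrium frequencies are uniform; there is no crossover interference
and no sex-chromosome special-casing.  Certain dosage calls can be
blurred with Dirichlet noise to emulate genotype-probability uncertainty.

Traits are sums of planted components, each standardized empirically so
configured variance fractions are realized: founder-dosage QTL effects,
covariate effects, a polygenic term drawn from the overall kinship, and
iid noise.  Mediation links build the mediator first and then compose the
target from the mediator plus optional direct QTL leakage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    FOUNDER_LABELS,
    CovariateColumn,
    CovariateMatrix,
    FounderSNPTable,
    GenoProbs,
    MarkerMap,
    Study,
    TraitMatrix,
)
from .kinship import compute_kinship
from .snps import sdp_mask

__all__ = [
    "ChromSpec",
    "QTLSpec",
    "TraitSpec",
    "MediationLink",
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_founder_snps",
    "simulate_covariates",
    "simulate_traits",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_cM: float = 80.0
    length_Mbp: float = 100.0
    n_markers: int = 100


@dataclass(frozen=True)
class QTLSpec:
    """A planted locus effect: an 8-founder effect vector or a biallelic SDP."""

    chrom: str
    marker_index: int
    var_frac: float
    effects: tuple[float, ...] | None = None  # length 8, trait-scale shape
    sdp: int | None = None  # alternative to effects: carriers get +1

    def effect_vector(self) -> np.ndarray:
        if self.effects is not None:
            v = np.asarray(self.effects, dtype=float)
            if v.shape != (8,):
                raise ValueError("QTL effect vector must have length 8")
            return v
        if self.sdp is not None:
            return sdp_mask(self.sdp).astype(float)
        raise ValueError("QTLSpec needs either effects or sdp")


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    qtls: tuple[QTLSpec, ...] = ()
    h2: float = 0.0  # polygenic variance fraction
    covar_fracs: dict[str, float] = field(default_factory=dict)
    annotation: tuple[str, float] | None = None  # (chromosome, midpoint_Mbp)

    def variance_fractions(self) -> list[float]:
        return [q.var_frac for q in self.qtls] + [self.h2] + list(self.covar_fracs.values())


@dataclass(frozen=True)
class MediationLink:
    """Causal chain QTL -> mediator -> target.

    ``beta_frac`` is the fraction of target variance explained by the
    mediator; ``leakage_frac`` is any direct QTL effect on the target.
    """

    mediator_id: str
    target_id: str
    beta_frac: float
    leakage_frac: float = 0.0
    sign: int = 1


@dataclass
class SimConfig:
    seed: int
    n_individuals: int = 200
    chromosomes: tuple[ChromSpec, ...] = (ChromSpec("1"), ChromSpec("2"))
    generations: float = 20.0
    dirichlet_concentration: float | None = 200.0
    covariate_names: tuple[str, ...] = ("sex",)
    traits: tuple[TraitSpec, ...] = ()
    mediation: tuple[MediationLink, ...] = ()
    snp_density_per_Mbp: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for t in self.traits:
            fracs = t.variance_fractions()
            if any(f < 0 or f >= 1 for f in fracs):
                raise ValueError(f"trait {t.trait_id}: variance fractions must be in [0, 1)")
            if sum(fracs) >= 1:
                raise ValueError(f"trait {t.trait_id}: variance fractions sum to >= 1")


@dataclass
class SimTruth:
    """Ground truth of a simulated study, JSON-serializable."""

    qtl: dict[str, list[dict]] = field(default_factory=dict)
    h2: dict[str, float] = field(default_factory=dict)
    mediators: dict[str, str] = field(default_factory=dict)  # target -> mediator

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> tuple[GenoProbs, MarkerMap]:
    """Founder-mosaic genotype probabilities and a matching marker map."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"DO{i + 1:04d}" for i in range(n)]
    probs: dict[str, np.ndarray] = {}
    map_rows = []
    for spec in config.chromosomes:
        if spec.n_markers < 1:
            raise ValueError(f"chromosome {spec.name}: needs at least 1 marker")
        pos_Mbp = np.linspace(0.0, spec.length_Mbp, spec.n_markers + 1)[1:]
        pos_cM = pos_Mbp * (spec.length_cM / spec.length_Mbp)
        for i, (mb, cm) in enumerate(zip(pos_Mbp, pos_cM)):
            map_rows.append(
                {
                    "marker_id": f"c{spec.name}_m{i + 1:04d}",
                    "chromosome": spec.name,
                    "pos_cM": float(cm),
                    "pos_Mbp": float(mb),
                }
            )
        # two haplotype chains per individual, vectorized across (n, 2)
        haps = np.empty((n, 2, spec.n_markers), dtype=np.int8)
        haps[:, :, 0] = rng.integers(0, 8, size=(n, 2))
        d_cM = np.diff(pos_cM)
        p_rec = 1.0 - np.exp(-config.generations * d_cM / 100.0)
        for m in range(1, spec.n_markers):
            rec = rng.random(size=(n, 2)) < p_rec[m - 1]
            new = rng.integers(0, 8, size=(n, 2))
            haps[:, :, m] = np.where(rec, new, haps[:, :, m - 1])
        dosage = np.zeros((n, 8, spec.n_markers))
        for h in range(2):
            np.add.at(
                dosage,
                (np.arange(n)[:, None], haps[:, h, :], np.arange(spec.n_markers)[None, :]),
                0.5,
            )
        if config.dirichlet_concentration is not None:
            conc = config.dirichlet_concentration
            alpha = conc * dosage + 0.5
            draws = rng.standard_gamma(alpha.transpose(0, 2, 1))  # (n, m, 8)
            draws /= draws.sum(axis=2, keepdims=True)
            dosage = draws.transpose(0, 2, 1)
        probs[spec.name] = dosage
    marker_map = MarkerMap(pd.DataFrame(map_rows))
    return GenoProbs(probs, ids), marker_map


# ---------------------------------------------------------------------------
# founder SNPs


def simulate_founder_snps(
    config: SimConfig, density_per_Mbp: float | None = None, seed: int | None = None
) -> FounderSNPTable:
    """Uniform-random founder SNPs with SDPs drawn from 1..254."""
    density = config.snp_density_per_Mbp if density_per_Mbp is None else density_per_Mbp
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for spec in config.chromosomes:
        count = int(rng.poisson(density * spec.length_Mbp)) if density > 0 else 0
        pos = np.sort(rng.uniform(0.0, spec.length_Mbp, size=count))
        sdp = rng.integers(1, 255, size=count)
        for i in range(count):
            rows.append(
                {
                    "snp_id": f"snp_{spec.name}_{i + 1:06d}",
                    "chr": spec.name,
                    "pos_Mbp": float(pos[i]),
                    "ref": "A",
                    "alt": "G",
                    "sdp": int(sdp[i]),
                    "csq": "intergenic_variant",
                }
            )
    frame = pd.DataFrame(rows, columns=["snp_id", "chr", "pos_Mbp", "ref", "alt", "sdp", "csq"])
    return FounderSNPTable(frame)


# ---------------------------------------------------------------------------
# covariates and traits


def simulate_covariates(config: SimConfig, individual_ids: list[str]) -> CovariateMatrix:
    """Intercept plus treatment-coded binary factors (e.g. sex)."""
    rng = np.random.default_rng(config.seed + 2)
    data = {"intercept": np.ones(len(individual_ids))}
    cols = [CovariateColumn("intercept", "numeric", False)]
    for name in config.covariate_names:
        data[name] = rng.integers(0, 2, size=len(individual_ids)).astype(float)
        cols.append(CovariateColumn(name, "factor", True))
    return CovariateMatrix(pd.DataFrame(data, index=individual_ids), cols)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("planted component has zero variance")
    return (x - np.mean(x)) / sd


def simulate_traits(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    config: SimConfig,
    covariates: CovariateMatrix | None = None,
) -> tuple[TraitMatrix, SimTruth]:
    """Assemble trait values from planted architectures; returns ground truth."""
    rng = np.random.default_rng(config.seed + 3)
    n = genoprobs.n_individuals
    ids = genoprobs.individual_ids
    truth = SimTruth()

    poly_chol: np.ndarray | None = None
    if any(t.h2 > 0 for t in config.traits):
        mode = "overall" if len(genoprobs.chromosomes) >= 1 else "loco"
        K = compute_kinship(genoprobs, mode="overall").matrices["overall"]
        poly_chol = np.linalg.cholesky(K + 1e-8 * np.eye(n))

    values: dict[str, np.ndarray] = {}
    for spec in config.traits:
        total = 0.0
        y = np.zeros(n)
        truth.qtl[spec.trait_id] = []
        for q in spec.qtls:
            if q.chrom not in genoprobs.probs:
                raise ValueError(f"trait {spec.trait_id}: chromosome {q.chrom!r} not simulated")
            arr = genoprobs.probs[q.chrom]
            if not (0 <= q.marker_index < arr.shape[2]):
                raise ValueError(
                    f"trait {spec.trait_id}: marker index {q.marker_index} outside "
                    f"chromosome {q.chrom} ({arr.shape[2]} markers)"
                )
            component = arr[:, :, q.marker_index] @ q.effect_vector()
            y += np.sqrt(q.var_frac) * _standardize(component)
            total += q.var_frac
            sub = marker_map.for_chromosome(q.chrom)
            truth.qtl[spec.trait_id].append(
                {
                    "chromosome": q.chrom,
                    "marker_index": q.marker_index,
                    "marker_id": sub["marker_id"].iloc[q.marker_index],
                    "pos_Mbp": float(sub["pos_Mbp"].iloc[q.marker_index]),
                    "effects": q.effect_vector().tolist(),
                    "var_frac": q.var_frac,
                }
            )
        if spec.h2 > 0:
            g = poly_chol @ rng.standard_normal(n)
            y += np.sqrt(spec.h2) * _standardize(g)
            total += spec.h2
        for name, frac in spec.covar_fracs.items():
            if covariates is None or name not in covariates.values.columns:
                raise ValueError(f"trait {spec.trait_id}: covariate {name!r} unavailable")
            y += np.sqrt(frac) * _standardize(
                covariates.values[name].to_numpy(dtype=float)
            )
            total += frac
        noise = rng.standard_normal(n)
        y += np.sqrt(1.0 - total) * _standardize(noise)
        values[spec.trait_id] = y
        truth.h2[spec.trait_id] = spec.h2

    for link in config.mediation:
        if link.mediator_id not in values:
            raise ValueError(f"mediation link: mediator {link.mediator_id!r} not simulated")
        target = np.zeros(n)
        total = 0.0
        med = _standardize(values[link.mediator_id])
        target += link.sign * np.sqrt(link.beta_frac) * med
        total += link.beta_frac
        if link.leakage_frac > 0:
            qtl0 = truth.qtl.get(link.mediator_id, [])
            if not qtl0:
                raise ValueError("mediation leakage requires a QTL on the mediator")
            q = qtl0[0]
            arr = genoprobs.probs[q["chromosome"]]
            comp = arr[:, :, q["marker_index"]] @ np.asarray(q["effects"])
            target += np.sqrt(link.leakage_frac) * _standardize(comp)
            total += link.leakage_frac
        noise = rng.standard_normal(n)
        target += np.sqrt(1.0 - total) * _standardize(noise)
        if link.target_id in values:
            raise ValueError(f"mediation target {link.target_id!r} already defined")
        values[link.target_id] = target
        truth.mediators[link.target_id] = link.mediator_id
        truth.qtl.setdefault(link.target_id, truth.qtl.get(link.mediator_id, []))
        truth.h2.setdefault(link.target_id, 0.0)

    frame = pd.DataFrame(values, index=ids)
    ann_rows = []
    for spec in config.traits:
        if spec.annotation is not None:
            ann_rows.append(
                {
                    "trait_id": spec.trait_id,
                    "symbol": spec.trait_id,
                    "chromosome": spec.annotation[0],
                    "midpoint_Mbp": spec.annotation[1],
                }
            )
    annotations = pd.DataFrame(ann_rows) if ann_rows else None
    return TraitMatrix(frame, name="sim", annotations=annotations), truth


def simulate_study(config: SimConfig) -> tuple[Study, SimTruth]:
    """One-call study assembly: genome, covariates, traits, founder SNPs."""
    genoprobs, marker_map = simulate_genome(config)
    covariates = simulate_covariates(config, genoprobs.individual_ids)
    traits, truth = simulate_traits(genoprobs, marker_map, config, covariates)
    snps = (
        simulate_founder_snps(config) if config.snp_density_per_Mbp > 0 else None
    )
    study = Study(
        genoprobs=genoprobs,
        marker_map=marker_map,
        traits={"sim": traits},
        covariates=covariates,
        founder_snps=snps,
    )
    return study, truth


def write_truth(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (JSON-decoded) dictionary."""
    chroms = tuple(
        ChromSpec(**c) if isinstance(c, dict) else ChromSpec(str(c))
        for c in d.get("chromosomes", [{"name": "1"}, {"name": "2"}])
    )
    traits = []
    for t in d.get("traits", []):
        qtls = tuple(
            QTLSpec(
                chrom=str(q["chrom"]),
                marker_index=int(q["marker_index"]),
                var_frac=float(q["var_frac"]),
                effects=tuple(q["effects"]) if q.get("effects") else None,
                sdp=int(q["sdp"]) if q.get("sdp") else None,
            )
            for q in t.get("qtls", [])
        )
        ann = t.get("annotation")
        traits.append(
            TraitSpec(
                trait_id=str(t["trait_id"]),
                qtls=qtls,
                h2=float(t.get("h2", 0.0)),
                covar_fracs={k: float(v) for k, v in t.get("covar_fracs", {}).items()},
                annotation=(str(ann[0]), float(ann[1])) if ann else None,
            )
        )
    links = tuple(
        MediationLink(
            mediator_id=str(m["mediator_id"]),
            target_id=str(m["target_id"]),
            beta_frac=float(m["beta_frac"]),
            leakage_frac=float(m.get("leakage_frac", 0.0)),
            sign=int(m.get("sign", 1)),
        )
        for m in d.get("mediation", [])
    )
    if "seed" not in d or d["seed"] is None:
        raise ValueError("simulation config requires a seed")
    return SimConfig(
        seed=int(d["seed"]),
        n_individuals=int(d.get("n_individuals", 200)),
        chromosomes=chroms,
        generations=float(d.get("generations", 20.0)),
        dirichlet_concentration=(
            None
            if d.get("dirichlet_concentration", 200.0) is None
            else float(d.get("dirichlet_concentration", 200.0))
        ),
        covariate_names=tuple(d.get("covariate_names", ["sex"])),
        traits=tuple(traits),
        mediation=links,
        snp_density_per_Mbp=float(d.get("snp_density_per_Mbp", 0.0)),
    )
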