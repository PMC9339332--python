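"""Core domain types, the on-disk study-bundle format, and result serialization.

A *study bundle* is a directory with a ``control.json`` naming its
components: a marker map (CSV), per-chromosome genotype-probability arrays
(HDF5, one file per chromosome), one or more trait datasets (CSV, with
optional annotation CSVs), a covariate table (CSV) with column metadata,
and an optional founder SNP table (TSV).

All tabular files are UTF-8 with a header row; empty cells or ``.`` denote
missing values.  Positions are 1-based Mbp floats and chromosome labels are
strings (``"X"`` is an ordinary label).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FOUNDER_LABELS",
    "FOUNDER_STRAINS",
    "MarkerMap",
    "GenoProbs",
    "TraitMatrix",
    "CovariateColumn",
    "CovariateMatrix",
    "KinshipLOCO",
    "NullFit",
    "LODScan",
    "AlleleEffects",
    "FounderSNPTable",
    "MediationResult",
    "Study",
    "BundleError",
    "ValidationError",
    "AlignmentError",
    "read_bundle",
    "write_bundle",
    "export_results_json",
    "results_to_frame",
]

#: Single-letter founder codes, in SDP bit order (bit 0 = A ... bit 7 = H).
FOUNDER_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Conventional strain names behind the letter codes.
FOUNDER_STRAINS = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/ShiLtJ",
    "NZO/HlLtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)

PROB_TOL = 1e-6

MISSING_TOKENS = ("", ".", "NA", "nan")


class BundleError(Exception):
    """A bundle component is missing or unreadable."""


class ValidationError(Exception):
    """A component violates a structural invariant."""


class AlignmentError(Exception):
    """Individual or marker identifiers cannot be reconciled."""


# ---------------------------------------------------------------------------
# chromosome ordering helper


def _chrom_sort_key(label: str) -> tuple[int, int | str]:
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


def sort_chromosomes(labels: Iterable[str]) -> list[str]:
    """Order chromosome labels numerically, then lexically ('X' after 19)."""
    return sorted(set(labels), key=_chrom_sort_key)


# ---------------------------------------------------------------------------
# MarkerMap


@dataclass(frozen=True)
class MarkerMap:
    """Genome-wide marker index: id, chromosome, cM and Mbp positions."""

    frame: pd.DataFrame  # columns: marker_id, chromosome, pos_cM, pos_Mbp

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "pos_cM", "pos_Mbp"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"marker map missing columns: {sorted(missing)}")
        f = self.frame
        if f["marker_id"].duplicated().any():
            dups = f.loc[f["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValidationError(f"duplicate marker ids: {dups[:5]}")
        for chrom, sub in f.groupby("chromosome", sort=False):
            if not sub["pos_Mbp"].is_monotonic_increasing:
                raise ValidationError(f"markers on chromosome {chrom} not sorted by pos_Mbp")
            if not sub["pos_cM"].is_monotonic_increasing:
                raise ValidationError(f"pos_cM decreasing within chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return sort_chromosomes(self.frame["chromosome"])

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        sub = self.frame[self.frame["chromosome"] == str(chrom)]
        if sub.empty:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        return sub.reset_index(drop=True)

    def marker_index(self, marker_id: str) -> tuple[str, int]:
        """Return (chromosome, within-chromosome index) of a marker."""
        hit = self.frame.index[self.frame["marker_id"] == marker_id]
        if len(hit) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        chrom = str(self.frame.loc[hit[0], "chromosome"])
        sub = self.for_chromosome(chrom)
        return chrom, int(sub.index[sub["marker_id"] == marker_id][0])

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerMap) and self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# GenoProbs


@dataclass
class GenoProbs:
    """Per-chromosome founder-haplotype dosage probabilities.

    ``probs[chrom]`` has shape (n_individuals, 8, n_markers); each
    (individual, marker) slice across the 8 founders sums to one.
    """

    probs: dict[str, np.ndarray]
    individual_ids: list[str]
    founder_labels: tuple[str, ...] = FOUNDER_LABELS

    def __post_init__(self) -> None:
        if len(self.founder_labels) != 8:
            raise ValidationError("exactly 8 founder labels required")
        n = len(self.individual_ids)
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual ids not unique")
        for chrom, arr in self.probs.items():
            if arr.ndim != 3 or arr.shape[0] != n or arr.shape[1] != 8:
                raise ValidationError(
                    f"chromosome {chrom}: expected shape ({n}, 8, markers), got {arr.shape}"
                )
            if np.nanmin(arr) < -PROB_TOL or np.nanmax(arr) > 1 + PROB_TOL:
                raise ValidationError(f"chromosome {chrom}: probabilities outside [0, 1]")
            sums = arr.sum(axis=1)
            bad = np.abs(sums - 1.0) > PROB_TOL
            if bad.any():
                i, m = np.argwhere(bad)[0]
                raise ValidationError(
                    f"chromosome {chrom}: probabilities for individual "
                    f"{self.individual_ids[i]!r} at marker index {m} sum to {sums[i, m]:.6g}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return sort_chromosomes(self.probs)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def subset(self, individual_ids: Sequence[str]) -> "GenoProbs":
        idx = [self.individual_ids.index(i) for i in individual_ids]
        return GenoProbs(
            probs={c: a[idx] for c, a in self.probs.items()},
            individual_ids=list(individual_ids),
            founder_labels=self.founder_labels,
        )

    def validate_against_map(self, marker_map: MarkerMap) -> None:
        for chrom, arr in self.probs.items():
            n_map = len(marker_map.for_chromosome(chrom))
            if arr.shape[2] != n_map:
                raise AlignmentError(
                    f"chromosome {chrom}: {arr.shape[2]} probability markers vs "
                    f"{n_map} map markers"
                )


# ---------------------------------------------------------------------------
# TraitMatrix


@dataclass
class TraitMatrix:
    """A named block of numeric traits over individuals (missing allowed)."""

    values: pd.DataFrame  # index = individual ids, columns = trait ids
    name: str = "traits"
    annotations: pd.DataFrame | None = None  # trait_id, symbol, chromosome, midpoint_Mbp
    transform: str = "raw"  # raw | norm | rz

    def __post_init__(self) -> None:
        if self.transform not in ("raw", "norm", "rz"):
            raise ValidationError(f"unknown transform tag {self.transform!r}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate trait ids")
        if self.annotations is not None and "trait_id" not in self.annotations.columns:
            raise ValidationError("annotations require a trait_id column")

    @property
    def trait_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def trait(self, trait_id: str) -> pd.Series:
        if trait_id not in self.values.columns:
            raise KeyError(f"trait {trait_id!r} not in dataset {self.name!r}")
        return self.values[trait_id]

    def scannable(self, trait_id: str) -> bool:
        return int(self.trait(trait_id).notna().sum()) >= 3

    def annotation_for(self, trait_id: str) -> pd.Series | None:
        if self.annotations is None:
            return None
        hit = self.annotations[self.annotations["trait_id"] == trait_id]
        return None if hit.empty else hit.iloc[0]


# ---------------------------------------------------------------------------
# CovariateMatrix


@dataclass(frozen=True)
class CovariateColumn:
    name: str
    kind: str = "numeric"  # numeric | factor
    interactive: bool = False


@dataclass
class CovariateMatrix:
    """Design matrix of covariates including an explicit intercept column.

    Factor covariates appear as treatment-coded indicator columns (reference
    level omitted); the ``interactive`` flag marks factors eligible for
    locus-by-factor interaction scans.
    """

    values: pd.DataFrame  # index = individual ids
    columns: list[CovariateColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if list(self.values.columns) != names:
            raise ValidationError("covariate metadata does not match design columns")
        if "intercept" not in names:
            raise ValidationError("covariate design must include an 'intercept' column")
        if not np.allclose(self.values["intercept"].to_numpy(dtype=float), 1.0):
            raise ValidationError("intercept column must be identically 1")
        arr = self.values.to_numpy(dtype=float)
        for i in range(arr.shape[1]):
            for j in range(i + 1, arr.shape[1]):
                if np.array_equal(arr[:, i], arr[:, j]):
                    raise ValidationError(
                        f"covariate columns {names[i]!r} and {names[j]!r} are identical"
                    )

    @property
    def individual_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def interactive_columns(self) -> list[str]:
        return [c.name for c in self.columns if c.interactive]

    def design(self, individual_ids: Sequence[str] | None = None) -> np.ndarray:
        frame = self.values if individual_ids is None else self.values.loc[list(individual_ids)]
        return frame.to_numpy(dtype=float)

    @classmethod
    def intercept_only(cls, individual_ids: Sequence[str]) -> "CovariateMatrix":
        return cls(
            values=pd.DataFrame({"intercept": 1.0}, index=list(individual_ids)),
            columns=[CovariateColumn("intercept", "numeric", False)],
        )


# ---------------------------------------------------------------------------
# KinshipLOCO


@dataclass
class KinshipLOCO:
    """Family of genetic relationship matrices keyed by left-out chromosome.

    ``mode == "overall"`` holds a single matrix under the key ``"overall"``.
    """

    matrices: dict[str, np.ndarray]
    individual_ids: list[str]
    mode: str = "loco"  # loco | overall

    SYM_TOL = 1e-10
    PSD_TOL = -1e-8

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        for key, K in self.matrices.items():
            if K.shape != (n, n):
                raise ValidationError(f"kinship {key}: shape {K.shape} != ({n}, {n})")
            if np.max(np.abs(K - K.T)) > self.SYM_TOL:
                raise ValidationError(f"kinship {key}: not symmetric")
            w = np.linalg.eigvalsh(K)
            if w.min() < self.PSD_TOL:
                raise ValidationError(f"kinship {key}: min eigenvalue {w.min():.3g} < 0")
            d = np.diag(K)
            if np.any(d <= 0) or np.any(d > 1 + 1e-8):
                raise ValidationError(f"kinship {key}: diagonal outside (0, 1]")

    def for_chromosome(self, chrom: str) -> np.ndarray:
        if self.mode == "overall":
            return self.matrices["overall"]
        if chrom not in self.matrices:
            raise KeyError(f"no LOCO kinship for chromosome {chrom!r}")
        return self.matrices[chrom]

    def subset(self, individual_ids: Sequence[str]) -> "KinshipLOCO":
        idx = np.asarray([self.individual_ids.index(i) for i in individual_ids])
        return KinshipLOCO(
            matrices={c: K[np.ix_(idx, idx)] for c, K in self.matrices.items()},
            individual_ids=list(individual_ids),
            mode=self.mode,
        )


# ---------------------------------------------------------------------------
# NullFit / LODScan / AlleleEffects


@dataclass
class NullFit:
    """REML fit of the no-QTL mixed model in the eigen-rotated basis.

    ``y_rot`` and ``x_rot`` are already whitened by the estimated variance
    weights, so downstream marker fits are ordinary least squares.
    """

    h2: float
    log10_likelihood: float
    y_rot: np.ndarray  # (n,) whitened rotated response
    x_rot: np.ndarray  # (n, p) whitened rotated covariates
    rotation: np.ndarray | None  # (n, n) V^T, or None for identity
    weights: np.ndarray  # (n,) variance weights h2*lam + (1-h2)
    rss0: float
    sigma2: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ValidationError(f"h2 {self.h2} outside [0, 1)")
        if not np.isfinite(self.log10_likelihood):
            raise ValidationError("non-finite null likelihood")

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Rotate and weight a column block to the working (OLS) basis."""
        M = np.asarray(M, dtype=float)
        if self.rotation is not None:
            M = self.rotation @ M
        return M / np.sqrt(self.weights)[:, None]


@dataclass
class LODScan:
    """Per-marker, per-trait LOD scores with their genomic coordinates."""

    lod: pd.DataFrame  # index = marker ids, one column per trait
    marker_map: pd.DataFrame  # marker_id, chromosome, pos_cM, pos_Mbp (scan order)
    kind: str = "additive"  # additive | full-interactive | interaction-delta
    used_kinship: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "full-interactive", "interaction-delta"):
            raise ValidationError(f"unknown scan kind {self.kind!r}")
        tol = 1e-6 if self.kind == "interaction-delta" else 1e-8
        arr = self.lod.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < -tol:
            raise ValidationError(f"negative LOD below tolerance in {self.kind} scan")

    @property
    def trait_ids(self) -> list[str]:
        return [str(c) for c in self.lod.columns]

    def max_marker(self, trait_id: str) -> tuple[str, float]:
        col = self.lod[trait_id]
        mk = str(col.idxmax())
        return mk, float(col.max())


@dataclass
class AlleleEffects:
    """Founder allele effects along one chromosome with per-marker LODs."""

    effects: pd.DataFrame  # index = marker ids, columns = 8 founder labels (raw scale)
    lod: pd.Series
    chromosome: str
    mode: str = "fixed"  # fixed | blup
    positions: pd.Series | None = None  # pos_Mbp aligned to markers

    def __post_init__(self) -> None:
        if self.effects.shape[1] != 8:
            raise ValidationError("allele effects require 8 founder columns")
        if self.mode not in ("fixed", "blup"):
            raise ValidationError(f"unknown effects mode {self.mode!r}")

    def centered(self) -> pd.DataFrame:
        """Display form: effects centered to sum to zero across founders."""
        return self.effects.sub(self.effects.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# Founder SNPs


SNP_COLUMNS = ["snp_id", "chr", "pos_Mbp", "ref", "alt", "sdp", "csq"]


@dataclass
class FounderSNPTable:
    """Biallelic founder variants with 8-bit strain distribution patterns.

    Bit f of ``sdp`` is set iff founder f (A/J = bit 0 ... WSB/EiJ = bit 7)
    carries the alternate allele; 0 and 255 are non-segregating and rejected.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SNP_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"founder SNP table missing columns: {sorted(missing)}")
        sdp = self.frame["sdp"].to_numpy()
        if len(sdp) and (np.any(sdp < 1) or np.any(sdp > 254)):
            raise ValidationError("sdp values must lie in 1..254 (0/255 are monomorphic)")
        if self.frame["snp_id"].duplicated().any():
            raise ValidationError("duplicate snp ids")

    def in_region(self, chrom: str, lo: float, hi: float) -> pd.DataFrame:
        f = self.frame
        sel = (f["chr"].astype(str) == str(chrom)) & (f["pos_Mbp"] >= lo) & (f["pos_Mbp"] <= hi)
        return f[sel].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class MediationResult:
    """Conditional LODs for one target locus across candidate mediators."""

    frame: pd.DataFrame  # mediator_id, chromosome, midpoint_Mbp, conditional_lod,
    #                      marginal_lod, n_used, degenerate
    target_id: str = ""
    chromosome: str = ""
    marker_id: str = ""

    def __post_init__(self) -> None:
        needed = {"mediator_id", "conditional_lod", "marginal_lod", "n_used"}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValidationError(f"mediation frame missing columns: {sorted(missing)}")
        lods = self.frame["conditional_lod"].to_numpy(dtype=float)
        if len(lods) and np.nanmin(lods) < -1e-8:
            raise ValidationError("negative conditional LOD")


# ---------------------------------------------------------------------------
# Study container


@dataclass
class Study:
    """A fully aligned study: probabilities, map, traits, covariates, SNPs."""

    genoprobs: GenoProbs
    marker_map: MarkerMap
    traits: dict[str, TraitMatrix]
    covariates: CovariateMatrix
    founder_snps: FounderSNPTable | None = None

    @property
    def individual_ids(self) -> list[str]:
        return self.genoprobs.individual_ids

    def dataset(self, name: str) -> TraitMatrix:
        if name not in self.traits:
            raise KeyError(f"unknown trait dataset {name!r}; have {sorted(self.traits)}")
        return self.traits[name]


# ---------------------------------------------------------------------------
# bundle reading / writing


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)


def _align_individuals(
    geno_ids: list[str], other_ids: Sequence[str], what: str
) -> list[str]:
    """Intersect ids, keeping genoprob order; warn on partial overlap >= 50%."""
    other = set(map(str, other_ids))
    shared = [i for i in geno_ids if i in other]
    frac = len(shared) / max(len(geno_ids), 1)
    if frac < 0.5:
        missing = [i for i in geno_ids if i not in other]
        raise AlignmentError(
            f"{what}: only {len(shared)}/{len(geno_ids)} genotyped individuals present "
            f"(first missing: {missing[:5]})"
        )
    if len(shared) < len(geno_ids) or len(other) > len(shared):
        warnings.warn(
            f"{what}: using intersection of {len(shared)} individuals "
            f"({len(geno_ids)} genotyped, {len(other)} in component)",
            stacklevel=3,
        )
    return shared


def read_bundle(path: str | Path) -> Study:
    """Load and cross-validate a study bundle directory."""
    root = Path(path)
    control_path = root / "control.json"
    if not control_path.exists():
        raise BundleError(f"missing control file: {control_path}")
    control = json.loads(control_path.read_text())

    def component(rel: str) -> Path:
        p = root / rel
        if not p.exists():
            raise BundleError(f"missing bundle component: {p}")
        return p

    # marker map
    map_frame = _read_csv(component(control["map"]))
    map_frame["chromosome"] = map_frame["chromosome"].astype(str)
    map_frame["marker_id"] = map_frame["marker_id"].astype(str)
    marker_map = MarkerMap(map_frame)

    # genotype probabilities
    probs: dict[str, np.ndarray] = {}
    individual_ids: list[str] | None = None
    founder_labels: tuple[str, ...] = FOUNDER_LABELS
    for chrom, rel in control["geno_probs"].items():
        with h5py.File(component(rel), "r") as h5:
            arr = np.asarray(h5["probs"], dtype=float)
            ids = [s.decode() for s in h5["individual_ids"][()]]
            founder_labels = tuple(s.decode() for s in h5["founder_labels"][()])
        if individual_ids is None:
            individual_ids = ids
        elif ids != individual_ids:
            raise AlignmentError(f"chromosome {chrom}: individual order differs across files")
        probs[str(chrom)] = arr
    if individual_ids is None:
        raise BundleError("control file declares no genotype probabilities")
    genoprobs = GenoProbs(probs, individual_ids, founder_labels)
    genoprobs.validate_against_map(marker_map)

    # covariates
    cov_entry = control["covariates"]
    cov_frame = _read_csv(component(cov_entry["file"]))
    cov_frame = cov_frame.set_index(cov_frame.columns[0])
    cov_frame.index = cov_frame.index.astype(str).rename(None)
    columns = [
        CovariateColumn(c["name"], c.get("kind", "numeric"), bool(c.get("interactive", False)))
        for c in cov_entry["columns"]
    ]
    shared = _align_individuals(individual_ids, cov_frame.index, "covariates")
    genoprobs = genoprobs.subset(shared) if shared != individual_ids else genoprobs
    covariates = CovariateMatrix(cov_frame.loc[shared], columns)

    # traits
    traits: dict[str, TraitMatrix] = {}
    for entry in control["traits"]:
        frame = _read_csv(component(entry["file"]))
        frame = frame.set_index(frame.columns[0])
        frame.index = frame.index.astype(str).rename(None)
        if frame.shape[1] == 0:
            raise BundleError(f"trait dataset {entry['id']!r} has no trait columns")
        ids = _align_individuals(genoprobs.individual_ids, frame.index, f"traits[{entry['id']}]")
        frame = frame.loc[ids].apply(pd.to_numeric)
        annotations = None
        if entry.get("annotations"):
            annotations = _read_csv(component(entry["annotations"]))
            annotations["trait_id"] = annotations["trait_id"].astype(str)
        traits[entry["id"]] = TraitMatrix(
            values=frame,
            name=entry["id"],
            annotations=annotations,
            transform=entry.get("transform", "raw"),
        )
    if not traits:
        raise BundleError("control file declares no trait datasets")

    # shrink everything to the common individual set (traits may drop further
    # individuals per-dataset; scans intersect per analysis)
    founder_snps = None
    if control.get("founder_snps"):
        snp_frame = pd.read_csv(
            component(control["founder_snps"]),
            sep="\t",
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
        snp_frame["chr"] = snp_frame["chr"].astype(str)
        founder_snps = FounderSNPTable(snp_frame)

    return Study(
        genoprobs=genoprobs,
        marker_map=marker_map,
        traits=traits,
        covariates=covariates,
        founder_snps=founder_snps,
    )


def write_bundle(study: Study, path: str | Path) -> Path:
    """Write a study to a bundle directory; output is byte-stable per input."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    for name, tm in study.traits.items():
        if tm.values.shape[1] == 0:
            raise ValidationError(f"trait dataset {name!r} is empty; refusing to write")

    control: dict = {"schema": "mppqtl-bundle-1"}

    control["map"] = "markers.csv"
    study.marker_map.frame.to_csv(root / "markers.csv", index=False)

    control["geno_probs"] = {}
    (root / "genoprobs").mkdir(exist_ok=True)
    for chrom in study.genoprobs.chromosomes:
        rel = f"genoprobs/chr{chrom}.h5"
        control["geno_probs"][chrom] = rel
        with h5py.File(root / rel, "w", track_order=True) as h5:
            h5.create_dataset(
                "probs", data=study.genoprobs.probs[chrom], track_times=False
            )
            h5.create_dataset(
                "individual_ids",
                data=np.array([s.encode() for s in study.genoprobs.individual_ids]),
                track_times=False,
            )
            h5.create_dataset(
                "founder_labels",
                data=np.array([s.encode() for s in study.genoprobs.founder_labels]),
                track_times=False,
            )

    control["covariates"] = {
        "file": "covariates.csv",
        "columns": [
            {"name": c.name, "kind": c.kind, "interactive": c.interactive}
            for c in study.covariates.columns
        ],
    }
    cov = study.covariates.values.copy()
    cov.insert(0, "individual_id", cov.index)
    cov.to_csv(root / "covariates.csv", index=False)

    control["traits"] = []
    for name, tm in study.traits.items():
        rel = f"traits_{name}.csv"
        entry: dict = {"id": name, "file": rel, "transform": tm.transform}
        vals = tm.values.copy()
        vals.insert(0, "individual_id", vals.index)
        vals.to_csv(root / rel, index=False)
        if tm.annotations is not None:
            arel = f"traits_{name}_annot.csv"
            tm.annotations.to_csv(root / arel, index=False)
            entry["annotations"] = arel
        control["traits"].append(entry)

    if study.founder_snps is not None:
        control["founder_snps"] = "founder_snps.tsv"
        study.founder_snps.frame.to_csv(root / "founder_snps.tsv", sep="\t", index=False)

    (root / "control.json").write_text(json.dumps(control, indent=2, sort_keys=True) + "\n")
    return root


def bundle_content_hash(path: str | Path) -> str:
    """SHA-256 over all files of a bundle, in sorted relative-path order."""
    root = Path(path)
    digest = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            digest.update(str(p.relative_to(root)).encode())
            digest.update(p.read_bytes())
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# result serialization

SCHEMA_VERSION = "mppqtl-results-1"


def results_to_frame(result) -> pd.DataFrame:
    """Flatten any result object into a tidy DataFrame (the CSV twin)."""
    if isinstance(result, LODScan):
        frame = result.marker_map[["marker_id", "chromosome", "pos_Mbp"]].copy()
        for trait in result.trait_ids:
            frame[f"lod_{trait}"] = result.lod[trait].to_numpy()
        return frame
    if isinstance(result, AlleleEffects):
        frame = result.effects.copy()
        frame.insert(0, "marker_id", frame.index)
        if result.positions is not None:
            frame["pos_Mbp"] = result.positions.to_numpy()
        frame["lod"] = result.lod.to_numpy()
        return frame.reset_index(drop=True)
    if isinstance(result, MediationResult):
        return result.frame.copy()
    if isinstance(result, pd.DataFrame):
        return result.copy()
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def _json_records(frame: pd.DataFrame) -> list[dict]:
    records = []
    for _, row in frame.iterrows():
        rec = {}
        for key, val in row.items():
            if isinstance(val, (np.floating, float)):
                val = None if pd.isna(val) else float(val)
            elif isinstance(val, np.integer):
                val = int(val)
            elif pd.isna(val):
                val = None
            rec[str(key)] = val
        records.append(rec)
    return records


def export_results_json(result, kind: str | None = None) -> str:
    """Serialize a result object to schema-versioned JSON text.

    Numbers are kept at full double precision (repr round-trip); key order
    is stable across runs.
    """
    frame = results_to_frame(result)
    if kind is None:
        kind = {
            LODScan: "lod_scan",
            AlleleEffects: "allele_effects",
            MediationResult: "mediation",
        }.get(type(result), "table")
    payload: dict = {"schema": SCHEMA_VERSION, "kind": kind}
    if isinstance(result, LODScan):
        payload["scan_kind"] = result.kind
    if isinstance(result, AlleleEffects):
        payload["mode"] = result.mode
        payload["chromosome"] = result.chromosome
    if isinstance(result, MediationResult):
        payload["target_id"] = result.target_id
        payload["locus"] = {"chromosome": result.chromosome, "marker_id": result.marker_id}
    payload["records"] = _json_records(frame)
    return json.dumps(payload, indent=2, sort_keys=False)
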