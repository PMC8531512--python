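"""Genotype handling: readers, quality control, imputation and the GRM.

Genotypes are biallelic SNP dosages in {0, 1, 2} (count of the minor
allele) with ``NaN`` for missing calls, held as a lines-by-markers float
matrix alongside a marker map (marker id, chromosome, position in Mb).

The quality-control filters mirror standard GBS practice for wheat
panels: drop low-call-rate samples first, then low-call-rate markers,
then markers whose minor allele frequency (computed on the surviving
samples) falls below the threshold.  Missing calls are filled by a
declared naive imputation (per-marker mean or mode) rather than a
haplotype-based imputer; at post-QC missingness levels this has a
negligible effect on the relationship matrix.

The genomic relationship matrix follows the first VanRaden construction
with allele frequencies estimated from the data:

    W = M - 2 p,   G = W W' / (2 sum_m p_m (1 - p_m)),

plus a small diagonal shrinkage ``eps`` so that G is always invertible
inside the mixed-model engine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "GRM",
    "DensityReport",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
    "impute_missing",
    "marker_density",
    "compute_grm",
]

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["marker_id", "chromosome", "position"]

# IUPAC ambiguity codes for heterozygous single-letter genotype calls
_IUPAC_HET = {
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
}
_MISSING_CODES = {"N", "NN", "--", "-", "NA", ""}


class GenotypeParseError(ValueError):
    """A genotype file failed to parse under the declared dialect."""


@dataclass
class GenotypeMatrix:
    """Lines-by-markers dosage matrix with a marker map.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing
    (mean imputation produces real-valued entries).
    """

    dosages: np.ndarray
    line_ids: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.line_ids = np.asarray(self.line_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (lines x markers)")
        if len(self.line_ids) != self.dosages.shape[0]:
            raise ValueError("line_ids length does not match dosage rows")
        if len(self.line_ids) != len(set(self.line_ids)):
            raise ValueError("line_ids are not unique")
        missing = [c for c in MAP_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker map lacks columns {missing}")
        if len(self.markers) != self.dosages.shape[1]:
            raise ValueError("marker map length does not match dosage columns")
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("marker ids are not unique")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.line_ids, columns=self.markers["marker_id"]
        )

    def subset(self, lines=None, markers=None) -> "GenotypeMatrix":
        """Positional subset along lines and/or markers."""
        lines = np.arange(self.n_lines) if lines is None else np.asarray(lines)
        markers = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(lines, markers)],
            line_ids=self.line_ids[lines],
            markers=self.markers.iloc[markers].reset_index(drop=True),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Filters applied to a genotype matrix, each in [0, 1].

    Defaults are the conventional GBS thresholds for wheat panels:
    samples kept at call rate > 0.8, markers at call rate > 0.7 and
    MAF >= 0.05.
    """

    maf_min: float = 0.05
    marker_call_min: float = 0.7
    sample_call_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_call_min", "sample_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    thresholds: QCThresholds
    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, removed: int, kept: int) -> None:
        self.steps.append({"step": step, "removed": removed, "kept": kept})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


@dataclass
class GRM:
    """Genomic relationship matrix over a set of lines."""

    values: np.ndarray
    line_ids: np.ndarray
    method: str = "vanraden1"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids)
        if self.values.shape != (len(self.line_ids),) * 2:
            raise ValueError("GRM shape does not match line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        return np.array([lookup[i] for i in ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


@dataclass
class DensityReport:
    """Marker density summary in Mb per marker (lower = denser)."""

    genome_size_mb: float
    n_markers: int
    overall_mb_per_marker: float
    per_chromosome: pd.DataFrame  # chromosome, n_markers, length_mb, mb_per_marker


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_genotypes(g: GenotypeMatrix, path, map_path=None) -> None:
    """Write a tab-separated lines-by-markers dosage matrix plus map sidecar."""
    path = Path(path)
    g.to_frame().to_csv(path, sep="\t", index_label="line_id", na_rep="NA")
    if map_path is None:
        map_path = path.with_suffix(path.suffix + ".map")
    g.markers[MAP_COLUMNS].to_csv(map_path, sep="\t", index=False)


def read_genotypes(path, format: str = "matrix", map_path=None) -> GenotypeMatrix:
    """Read genotype calls as minor-allele dosages.

    Formats: ``matrix`` (TSV written by :func:`write_genotypes`, with an
    optional map sidecar), ``vcf`` (biallelic records only; multi-allelic
    sites are dropped with a logged count) and ``hapmap`` (tab-separated
    HapMap-style table with single-letter IUPAC genotype codes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix":
        return _read_matrix(path, map_path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix(path: Path, map_path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc
    try:
        dosages = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-numeric dosage entry ({exc})") from exc
    bad = dosages[np.isfinite(dosages)]
    if bad.size and (np.nanmin(bad) < 0 or np.nanmax(bad) > 2):
        raise GenotypeParseError(f"{path}: dosages outside [0, 2]")
    if map_path is None:
        candidate = path.with_suffix(path.suffix + ".map")
        map_path = candidate if candidate.exists() else None
    if map_path is not None:
        markers = pd.read_csv(map_path, sep="\t")
        if list(markers["marker_id"]) != list(df.columns):
            raise GenotypeParseError(f"{map_path}: marker ids do not match matrix columns")
    else:
        markers = pd.DataFrame(
            {"marker_id": df.columns, "chromosome": "un", "position": np.arange(df.shape[1], dtype=float)}
        )
    return GenotypeMatrix(dosages, df.index.to_numpy(), markers)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc
    samples = np.array(vcf.samples)
    rows, ids, chroms, pos = [], [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(float)
        dosage = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dosage)
        ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        chroms.append(variant.CHROM)
        pos.append(variant.POS / 1e6)  # VCF POS is 1-based bp
    if n_multi:
        logger.info("%s: dropped %d multi-allelic record(s)", path, n_multi)
    if not rows:
        raise GenotypeParseError(f"{path}: no biallelic records")
    dosages = np.column_stack(rows) if len(samples) else np.empty((0, len(rows)))
    markers = pd.DataFrame({"marker_id": ids, "chromosome": chroms, "position": pos})
    return _recode_to_minor(GenotypeMatrix(dosages, samples, markers))


def _read_hapmap(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc
    meta_cols = 11
    if df.shape[1] <= meta_cols:
        raise GenotypeParseError(f"{path}: no sample columns after the 11 metadata columns")
    samples = np.array(df.columns[meta_cols:])
    dosages = np.full((len(samples), len(df)), np.nan)
    for m, (_, row) in enumerate(df.iterrows()):
        alleles = str(row.iloc[1]).split("/")
        if len(alleles) != 2:
            raise GenotypeParseError(f"{path}: line {m + 2}: alleles field {row.iloc[1]!r}")
        ref, alt = alleles
        for s, call in enumerate(row.iloc[meta_cols:]):
            call = str(call).strip().upper()
            if call in _MISSING_CODES:
                continue
            if len(call) == 2:  # two-letter calls, e.g. "AG"
                dosages[s, m] = sum(c == alt for c in call)
            elif call == ref:
                dosages[s, m] = 0.0
            elif call == alt:
                dosages[s, m] = 2.0
            elif call in _IUPAC_HET and _IUPAC_HET[call] == {ref, alt}:
                dosages[s, m] = 1.0
            else:
                raise GenotypeParseError(
                    f"{path}: line {m + 2}: call {call!r} incompatible with alleles {ref}/{alt}"
                )
    markers = pd.DataFrame(
        {
            "marker_id": df.iloc[:, 0].to_numpy(),
            "chromosome": df.iloc[:, 2].to_numpy(),
            "position": pd.to_numeric(df.iloc[:, 3]) / 1e6,
        }
    )
    return _recode_to_minor(GenotypeMatrix(dosages, samples, markers))


def _recode_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip marker coding so dosages count the minor allele."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(g.dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        g.dosages[:, flip] = 2.0 - g.dosages[:, flip]
    return g


# ---------------------------------------------------------------------------
# QC / imputation
# ---------------------------------------------------------------------------


def _call_rate(x: np.ndarray, axis: int) -> np.ndarray:
    return 1.0 - np.isnan(x).mean(axis=axis)


def _maf(dosages: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def qc_filter(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three QC filters in a fixed order.

    1. drop samples with call rate <= ``sample_call_min``;
    2. drop markers with call rate <= ``marker_call_min`` (on surviving
       samples);
    3. drop markers with MAF < ``maf_min`` computed on surviving samples.

    MAF depends on the retained sample set, hence samples go first; the
    order is recorded in the report.
    """
    if t is None:
        t = QCThresholds()
    report = QCReport(thresholds=t)

    keep_lines = np.where(_call_rate(g.dosages, axis=1) > t.sample_call_min)[0]
    # a zero threshold is vacuous: keep everything, incl. all-missing rows
    if t.sample_call_min == 0.0:
        keep_lines = np.arange(g.n_lines)
    if keep_lines.size == 0:
        raise ValueError("qc_filter: sample call-rate step removed every sample")
    report.add("sample_call_rate", g.n_lines - keep_lines.size, keep_lines.size)
    g = g.subset(lines=keep_lines)

    keep = np.where(_call_rate(g.dosages, axis=0) > t.marker_call_min)[0]
    if t.marker_call_min == 0.0:
        keep = np.arange(g.n_markers)
    if keep.size == 0:
        raise ValueError("qc_filter: marker call-rate step removed every marker")
    report.add("marker_call_rate", g.n_markers - keep.size, keep.size)
    g = g.subset(markers=keep)

    maf = _maf(g.dosages)
    keep = np.where(~(maf < t.maf_min))[0]  # NaN-MAF markers only occur at call_min=0
    if keep.size == 0:
        raise ValueError("qc_filter: MAF step removed every marker")
    report.add("maf", g.n_markers - keep.size, keep.size)
    g = g.subset(markers=keep)
    return g, report


def impute_missing(g: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing calls per marker; non-missing cells are untouched.

    ``marker_mean`` fills with the real-valued mean dosage, ``marker_mode``
    with the most frequent dosage (ties broken toward the smaller value).
    """
    if method not in ("marker_mean", "marker_mode"):
        raise ValueError(f"unknown imputation method {method!r}")
    x = g.dosages.copy()
    missing = np.isnan(x)
    if not missing.any():
        return GenotypeMatrix(x, g.line_ids.copy(), g.markers.copy())
    fully = missing.all(axis=0)
    if fully.any():
        raise ValueError(
            f"{int(fully.sum())} marker(s) entirely missing; run qc_filter first"
        )
    if method == "marker_mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmean(x, axis=0)
    else:
        fill = np.empty(g.n_markers)
        for m in range(g.n_markers):
            col = x[:, m]
            col = col[~np.isnan(col)]
            vals, counts = np.unique(col, return_counts=True)
            fill[m] = vals[np.argmax(counts)]
    idx = np.where(missing)
    x[idx] = fill[idx[1]]
    return GenotypeMatrix(x, g.line_ids.copy(), g.markers.copy())


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def marker_density(
    g: GenotypeMatrix,
    genome_size_mb: float,
    chrom_lengths: dict | None = None,
) -> DensityReport:
    """Average genome span per marker, overall and per chromosome.

    Per-chromosome lengths come from ``chrom_lengths`` (Mb) when given,
    otherwise from the largest mapped position on each chromosome.
    Values are kept at full precision; round only when reporting.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    if g.n_markers == 0:
        raise ValueError("no markers")
    per = (
        g.markers.groupby("chromosome", sort=False)
        .agg(n_markers=("marker_id", "size"), max_pos=("position", "max"))
        .reset_index()
    )
    if chrom_lengths is not None:
        per["length_mb"] = per["chromosome"].map(chrom_lengths)
    else:
        per["length_mb"] = per["max_pos"]
    per["mb_per_marker"] = per["length_mb"] / per["n_markers"]
    per = per.drop(columns="max_pos")
    return DensityReport(
        genome_size_mb=float(genome_size_mb),
        n_markers=g.n_markers,
        overall_mb_per_marker=float(genome_size_mb) / g.n_markers,
        per_chromosome=per,
    )


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def compute_grm(g: GenotypeMatrix, method: str = "vanraden1", epsilon: float = 1e-6) -> GRM:
    """VanRaden genomic relationship matrix with observed allele
    frequencies, plus ``epsilon`` on the diagonal for invertibility."""
    if method != "vanraden1":
        raise ValueError(f"unknown GRM method {method!r}")
    x = g.dosages
    if np.isnan(x).any():
        raise ValueError("genotypes contain missing calls; impute_missing first")
    p = x.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    W = x - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    G[np.diag_indices_from(G)] += epsilon
    return GRM(values=G, line_ids=g.line_ids.copy(), method=method, epsilon=epsilon)
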