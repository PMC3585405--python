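"""Data containers, readers/writers, scaling and QC shared by every pipeline stage.

The metabolome observable is a samples x features intensity matrix whose column
names encode per-feature mass-to-charge and retention time as ``"<mz>_<rt>"``
(e.g. ``"1056.528_226.57"`` is m/z 1056.528 eluting at 226.57 s).  Genotypes are
biallelic SNP dosages (0/1/2) with ids ``"S<chrom>_<pos>"``.  Phenotypes are
per-line real-valued traits.  All downstream stages consume these containers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "GenotypeMatrix",
    "ScaledMatrix",
    "parse_feature_id",
    "parse_snp_id",
    "read_feature_table",
    "write_feature_table",
    "read_genotypes",
    "read_phenotypes",
    "average_technical_replicates",
    "autoscale",
    "pareto_scale",
    "pca_summary",
]

_FEATURE_ID_RE = re.compile(r"^(\d+(?:\.\d+)?)_(\d+(?:\.\d+)?)$")
_SNP_ID_RE = re.compile(r"^S(\d+)_(\d+)$")


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Parse an ``"<mz>_<rt>"`` feature id into ``(mz, rt_seconds)``.

    Raises ``ValueError`` for any other dialect; the underscore separator and
    decimal points are the only accepted form.
    """
    m = _FEATURE_ID_RE.match(feature_id)
    if m is None:
        raise ValueError(f"feature id {feature_id!r} is not of the form '<mz>_<rt>'")
    return float(m.group(1)), float(m.group(2))


def parse_snp_id(snp_id: str) -> tuple[int, int]:
    """Parse ``"S<chrom>_<pos>"`` (e.g. ``"S7_18857356"``) into ``(chrom, pos)``."""
    m = _SNP_ID_RE.match(snp_id)
    if m is None:
        raise ValueError(f"SNP id {snp_id!r} is not of the form 'S<chrom>_<pos>'")
    return int(m.group(1)), int(m.group(2))


@dataclass
class FeatureTable:
    """Samples x molecular-features intensity matrix with per-feature m/z and RT.

    Parameters
    ----------
    intensities
        Non-negative DataFrame, index = sample ids, columns = feature ids.
    mz, rt
        Per-feature mass-to-charge (Da) and retention time (seconds), aligned
        with ``intensities.columns``.  ``NaN`` marks features whose id could
        not be parsed (kept only on request).
    channel
        ``"MS"`` for the low collision-energy channel, ``"MSE"`` for the high
        collision-energy (all-ion fragmentation) channel.
    """

    intensities: pd.DataFrame
    mz: pd.Series
    rt: pd.Series
    channel: str = "MS"

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if (vals < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.intensities.columns.duplicated().any():
            dup = self.intensities.columns[self.intensities.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        self.mz = self.mz.reindex(self.intensities.columns)
        self.rt = self.rt.reindex(self.intensities.columns)

    @classmethod
    def from_frame(cls, intensities: pd.DataFrame, channel: str = "MS",
                   on_bad_id: str = "raise") -> "FeatureTable":
        """Build a table from a plain DataFrame, parsing mz/rt from column names.

        ``on_bad_id``: ``"raise"`` rejects unparseable ids, ``"null"`` keeps the
        column with missing mz/rt metadata.
        """
        mz, rt = {}, {}
        for fid in intensities.columns:
            try:
                mz[fid], rt[fid] = parse_feature_id(str(fid))
            except ValueError:
                if on_bad_id == "null":
                    mz[fid], rt[fid] = np.nan, np.nan
                else:
                    raise
        return cls(intensities, pd.Series(mz), pd.Series(rt), channel=channel)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]


@dataclass
class GenotypeMatrix:
    """Lines x SNPs dosage matrix (0/1/2, NaN = missing) with map positions."""

    dosage: pd.DataFrame
    chrom: pd.Series = field(default=None)  # type: ignore[assignment]
    pos: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dosage.columns.duplicated().any():
            raise ValueError("duplicate SNP ids")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = vals[~ok].flat[0]
            raise ValueError(f"dosage value {bad!r} not in {{0,1,2,missing}}")
        if self.chrom is None or self.pos is None:
            chrom, pos = {}, {}
            for sid in self.dosage.columns:
                chrom[sid], pos[sid] = parse_snp_id(str(sid))
            self.chrom = pd.Series(chrom, dtype=int)
            self.pos = pd.Series(pos, dtype=int)

    @property
    def line_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    def minor_allele_freq(self) -> pd.Series:
        """Per-SNP minor allele frequency from observed dosages."""
        p = self.dosage.mean(axis=0, skipna=True) / 2.0
        return pd.concat([p, 1.0 - p], axis=1).min(axis=1)


@dataclass
class ScaledMatrix:
    """Column-scaled feature matrix plus the scaling tag and dropped columns.

    ``autoscale`` columns have mean 0 and sample SD (n-1 denominator) 1;
    ``pareto`` columns are centered and divided by the square root of the SD.
    """

    values: pd.DataFrame
    scaling: str
    dropped: list[str] = field(default_factory=list)


def read_feature_table(path, channel: str = "MS", sep: str | None = None,
                       on_bad_id: str = "raise") -> FeatureTable:
    """Read a delimited feature table: first column sample id, remaining columns
    ``"<mz>_<rt>"`` feature ids.  ``sep=None`` sniffs comma vs tab."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return FeatureTable.from_frame(df, channel=channel, on_bad_id=on_bad_id)


def write_feature_table(ft: FeatureTable, path, sep: str = ",") -> None:
    ft.intensities.to_csv(path, sep=sep, index_label="sample")


def read_genotypes(path, sep: str | None = None) -> GenotypeMatrix:
    """Read genotypes as numeric dosages or HapMap-style text.

    The numeric dialect is lines x SNPs with values in {0,1,2} (blank/NA =
    missing).  A HapMap-style file (tab-separated, columns ``rs#``, ``alleles``,
    ``chrom``, ``pos``, then one column per line, genotypes as allele-pair
    letters such as ``AA``/``AG`` or IUPAC single letters, ``NN``/``N`` missing)
    is detected from its header and converted to counts of the second listed
    allele.
    """
    with open(path) as fh:
        header = fh.readline()
    if header.split("\t")[0].strip() in ("rs#", "rs"):
        return _read_hapmap(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return GenotypeMatrix(df.astype(float))


def _read_hapmap(path) -> GenotypeMatrix:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = list(raw.columns[:4])
    line_cols = [c for c in raw.columns if c not in raw.columns[:11]]
    if not line_cols:  # compact dialect: rs#, alleles, chrom, pos, <lines...>
        line_cols = [c for c in raw.columns if c not in meta_cols]
    snp_ids, chrom, pos, rows = [], {}, {}, []
    iupac_het = set("RYSWKM")
    for _, rec in raw.iterrows():
        sid = str(rec.iloc[0])
        alleles = str(rec["alleles"]).split("/")
        if len(alleles) != 2:
            raise ValueError(f"SNP {sid!r} is not biallelic: {rec['alleles']!r}")
        a, b = alleles
        dos = []
        for call in rec[line_cols]:
            call = str(call).strip()
            if call in ("NN", "N", "nan", ""):
                dos.append(np.nan)
            elif len(call) == 1:
                dos.append(1.0 if call in iupac_het else
                           2.0 * (call == b) if call in (a, b) else _bad(sid, call))
            else:
                dos.append(float(sum(ch == b for ch in call))
                           if set(call) <= {a, b} else _bad(sid, call))
        snp_ids.append(sid)
        chrom[sid] = int(rec["chrom"])
        pos[sid] = int(rec["pos"])
        rows.append(dos)
    dosage = pd.DataFrame(np.array(rows).T, index=line_cols, columns=snp_ids)
    return GenotypeMatrix(dosage, pd.Series(chrom, dtype=int), pd.Series(pos, dtype=int))


def _bad(sid, call):
    raise ValueError(f"SNP {sid!r}: genotype call {call!r} not in declared alleles")


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Per-line phenotype table: first column line id, remaining columns traits."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     index_col=0)
    if df.index.duplicated().any():
        raise ValueError("phenotype table has duplicated line ids")
    df.index = df.index.astype(str)
    return df


def average_technical_replicates(ft: FeatureTable, replicate_map: dict[str, str]) -> FeatureTable:
    """Collapse technical-replicate injections to biological lines by the mean.

    ``replicate_map`` maps every injection (sample) id to its biological id.
    Raises on any unmapped sample.
    """
    missing = [s for s in ft.sample_ids if s not in replicate_map]
    if missing:
        raise KeyError(f"samples without a replicate mapping: {missing[:5]}")
    groups = ft.intensities.groupby(
        ft.intensities.index.map(replicate_map), sort=False)
    out = groups.mean()
    return FeatureTable(out, ft.mz.copy(), ft.rt.copy(), channel=ft.channel)


def _scale(ft, mode: str) -> ScaledMatrix:
    X = ft.intensities if isinstance(ft, FeatureTable) else pd.DataFrame(ft)
    if X.shape[0] < 2:
        raise ValueError("scaling requires at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(X.columns[~keep])
    X = X.loc[:, keep]
    sd = sd[keep]
    centered = X - X.mean(axis=0)
    scaled = centered / sd if mode == "autoscale" else centered / np.sqrt(sd)
    return ScaledMatrix(scaled, mode, dropped)


def autoscale(ft) -> ScaledMatrix:
    """Center each feature and divide by its sample SD (unit-variance columns).

    Autoscaling keeps dynamic high-abundance metabolites from dominating the
    correlation network.  Zero-variance columns are dropped and reported in
    ``ScaledMatrix.dropped``.
    """
    return _scale(ft, "autoscale")


def pareto_scale(ft) -> ScaledMatrix:
    """Center each feature and divide by the square root of its sample SD."""
    return _scale(ft, "pareto")


def pca_summary(sm: ScaledMatrix, ncomp: int) -> np.ndarray:
    """Fractions of total variance explained by the top ``ncomp`` PCs (QC only)."""
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    X = sm.values.to_numpy(dtype=float)
    if ncomp > min(X.shape):
        raise ValueError("ncomp exceeds matrix rank bound")
    X = X - X.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    frac = sv**2 / np.sum(sv**2)
    return frac[:ncomp]
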