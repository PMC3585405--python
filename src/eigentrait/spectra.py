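"""Spectral reconstruction from dual-channel feature tables and mass arithmetic.

Indiscriminant MS/MS (idMS/MS) reconstructs fragment spectra without precursor
isolation: features from the high collision-energy channel that elute within a
narrow retention-time window of the feature of interest (2 s on either side by
default) and whose intensities co-vary with it across samples (a correlational
filter) are collected as the fragment peaks of one compound.  The same grouping
on the low collision-energy channel reconstructs the MS spectrum, whose isotope
clusters reveal charge state (spacing 1.003355/z Da) and hence neutral mass.
Mass utilities cover elemental formulas, dehydration conjugates (e.g. the
phenylpropanoid amides of tyramine) and peptide monoisotopic masses, and
spectra are exported as NIST-dialect ``.msp`` libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass

from .io import FeatureTable

__all__ = [
    "Spectrum",
    "IsotopeCluster",
    "AnnotationRecord",
    "ISOTOPE_SPACING",
    "PROTON_MASS",
    "HYDROGEN_MASS",
    "rt_window_group",
    "correlation_filter",
    "reconstruct_idmsms",
    "detect_charge",
    "neutral_mass",
    "formula_monoisotopic",
    "protonated_mz",
    "conjugate_mz",
    "peptide_monoisotopic",
    "write_msp",
    "read_msp",
    "cosine_match",
]

ISOTOPE_SPACING = 1.003355  # 13C - 12C, Da
PROTON_MASS = 1.007276  # Da, for [M+H]+ adducts of small molecules
HYDROGEN_MASS = 1.00794  # Da, per-charge subtraction in peptide deconvolution

BASE_PEAK = 999.0


@dataclass
class Spectrum:
    """Peak list with intensities scaled so the base peak is exactly 999."""

    mz: np.ndarray
    intensity: np.ndarray
    kind: str = "MS"  # "MS" or "idMSMS"
    precursor_mz: float | None = None
    rt: float | None = None
    name: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size:
            if np.any(self.intensity <= 0):
                raise ValueError("peak intensities must be positive")
            peak = self.intensity.max()
            self.intensity = self.intensity * (BASE_PEAK / peak)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def is_empty(self) -> bool:
        return self.mz.size == 0


@dataclass
class IsotopeCluster:
    """An isotope envelope with inferred charge and monoisotopic mass."""

    mz: list[float]
    charge: int
    monoisotopic_mz: float
    mean_spacing: float

    def neutral_mass(self, m_h: float = HYDROGEN_MASS) -> float:
        return neutral_mass(self.monoisotopic_mz, self.charge, m_h=m_h)


@dataclass
class AnnotationRecord:
    """A proposed identity with its identification-confidence level (1-4)."""

    feature_id: str
    identity: str
    confidence_level: int
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.confidence_level not in (1, 2, 3, 4):
            raise ValueError("identification confidence level must be 1-4")


def rt_window_group(target_id: str, table: FeatureTable,
                    window: float = 2.0) -> list[str]:
    """Features eluting within ``window`` seconds of the target feature's RT
    (inclusive on both sides), target excluded."""
    if target_id not in table.rt.index or not np.isfinite(table.rt[target_id]):
        # the target may live in the other channel; fall back to parsing its id
        from .io import parse_feature_id
        _, rt0 = parse_feature_id(target_id)
    else:
        rt0 = float(table.rt[target_id])
    sel = table.rt.index[(table.rt - rt0).abs() <= window]
    return [f for f in sel if f != target_id]


def correlation_filter(table: FeatureTable, candidate_ids, target: np.ndarray,
                       r_min: float = 0.5) -> list[str]:
    """Keep candidates whose intensity profile correlates with the target at
    Pearson r >= r_min across samples; zero-variance candidates are dropped."""
    target = np.asarray(target, dtype=float)
    if target.size < 3:
        raise ValueError("correlational filter needs at least 3 samples")
    if target.std() == 0:
        raise ValueError("target profile has zero variance")
    kept = []
    for fid in candidate_ids:
        x = table.intensities[fid].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        r = float(np.corrcoef(x, target)[0, 1])
        if r >= r_min:
            kept.append(fid)
    return kept


def reconstruct_idmsms(target_id: str, low_ce: FeatureTable, high_ce: FeatureTable,
                       window: float = 2.0, r_min: float = 0.5) -> tuple[Spectrum, Spectrum]:
    """Reconstruct the MS and idMS/MS spectra of one feature of interest.

    The target must be a column of the low collision-energy table.  In each
    channel, candidates are gathered in the RT window around the target and
    passed through the correlational filter against the target's intensity
    profile; peak intensity is the median intensity across samples,
    renormalized to base peak 999.  An empty reconstruction yields an empty
    spectrum (``is_empty``) rather than an error.
    """
    if target_id not in low_ce.intensities.columns:
        raise KeyError(f"target {target_id!r} absent from the low-CE table")
    profile = low_ce.intensities[target_id].to_numpy(dtype=float)
    rt0 = float(low_ce.rt[target_id])
    specs = []
    for table, kind in ((low_ce, "MS"), (high_ce, "idMSMS")):
        cands = rt_window_group(target_id, table, window=window)
        kept = correlation_filter(table, cands, profile, r_min=r_min)
        if table is low_ce:
            kept = [target_id] + kept
        mzs, meds, prov = [], [], []
        for fid in kept:
            med = float(np.median(table.intensities[fid].to_numpy(dtype=float)))
            if med <= 0:
                continue
            mzs.append(float(table.mz[fid]))
            meds.append(med)
            prov.append(fid)
        specs.append(Spectrum(
            np.array(mzs), np.array(meds), kind=kind,
            precursor_mz=float(low_ce.mz[target_id]), rt=rt0,
            name=f"{target_id} {kind}", provenance=prov))
    return specs[0], specs[1]


def detect_charge(cluster_mz, tol_ppm: float = 20.0, max_z: int = 6) -> IsotopeCluster:
    """Infer charge state from isotope spacing.

    The mean spacing of the sorted member m/z values is matched against
    ``1.003355 / z``; every individual spacing must agree with the chosen z
    within ``2 * tol_ppm * 1e-6 * mean(mz)`` Da, else the cluster is rejected
    as irregular.  The monoisotopic peak is the lowest member.
    """
    mz = np.sort(np.asarray(cluster_mz, dtype=float))
    if mz.size < 2:
        raise ValueError("an isotope cluster needs at least 2 peaks")
    spacings = np.diff(mz)
    mean_sp = float(spacings.mean())
    z = int(round(ISOTOPE_SPACING / mean_sp))
    if z < 1 or z > max_z:
        raise ValueError(f"spacing {mean_sp:.5f} Da implies charge outside 1..{max_z}")
    tol = 2.0 * tol_ppm * 1e-6 * float(mz.mean())
    expected = ISOTOPE_SPACING / z
    if np.any(np.abs(spacings - expected) > tol):
        raise ValueError("irregular isotope spacing within the cluster")
    return IsotopeCluster(list(mz), z, float(mz[0]), mean_sp)


def neutral_mass(mz: float, z: int, m_h: float = HYDROGEN_MASS) -> float:
    """Neutral mass from an m/z at charge z: ``M = z * (mz - m_h)``.

    The per-charge subtraction defaults to the hydrogen-atom mass (1.00794),
    the convention that reproduces peptide molecular weights printed from
    multiply charged envelopes.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    if mz <= m_h:
        raise ValueError("m/z must exceed the per-charge mass")
    return z * (mz - m_h)


def formula_monoisotopic(formula: str) -> float:
    """Monoisotopic mass of an elemental formula over C,H,N,O,S,P (Da)."""
    if formula == "":
        return 0.0
    allowed = set("CHNOSP0123456789")
    if not set(formula) <= allowed:
        raise ValueError(f"formula {formula!r} contains unsupported elements")
    return float(_ptmass.calculate_mass(formula=formula))


def protonated_mz(formula: str, proton: float = PROTON_MASS) -> float:
    """[M+H]+ m/z of a neutral formula (adds the proton mass 1.007276)."""
    return formula_monoisotopic(formula) + proton


def conjugate_mz(formula_a: str, formula_b: str, loss: str = "H2O",
                 proton: float = PROTON_MASS) -> float:
    """[M+H]+ of a condensation conjugate: A + B - loss, protonated.

    Dehydration conjugates (loss = H2O) cover the phenylpropanoid amides, e.g.
    p-coumaric acid + tyramine - H2O -> coumaroyltyramine.
    """
    total = (formula_monoisotopic(formula_a) + formula_monoisotopic(formula_b))
    lost = formula_monoisotopic(loss) if loss else 0.0
    if lost >= total:
        raise ValueError("neutral loss exceeds the combined mass")
    return total - lost + proton


def peptide_monoisotopic(sequence: str) -> float:
    """Monoisotopic mass of a peptide (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    if not set(sequence) <= set(_ptmass.std_aa_mass):
        bad = sorted(set(sequence) - set(_ptmass.std_aa_mass))
        raise ValueError(f"unknown amino-acid letters: {bad}")
    return float(_ptmass.calculate_mass(sequence=sequence))


def write_msp(spectra, path) -> None:
    """Write spectra as a NIST-dialect .msp library (Name / PrecursorMZ /
    Num Peaks headers followed by ``mz intensity`` lines)."""
    with open(path, "w") as fh:
        for i, sp in enumerate(spectra):
            name = sp.name or f"spectrum_{i + 1}"
            fh.write(f"Name: {name}\n")
            if sp.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {sp.precursor_mz:.4f}\n")
            if sp.rt is not None:
                fh.write(f"RetentionTime: {sp.rt:.2f}\n")
            fh.write(f"Comment: kind={sp.kind}\n")
            fh.write(f"Num Peaks: {sp.n_peaks}\n")
            for m, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{m:.4f} {inten:.1f}\n")
            fh.write("\n")


def read_msp(path) -> list[Spectrum]:
    """Read a .msp library written by :func:`write_msp` (or a compatible NIST
    dialect).  Raises on records whose declared peak count disagrees."""
    spectra = []
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    expecting = 0

    def _flush():
        if not meta and not peaks:
            return
        declared = int(meta.get("num peaks", len(peaks)))
        if declared != len(peaks):
            raise ValueError(
                f"record {meta.get('name', '?')!r}: declared {declared} peaks, "
                f"found {len(peaks)}")
        kind = "MS"
        if "comment" in meta and "kind=" in meta["comment"]:
            kind = meta["comment"].split("kind=")[1].split()[0]
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        spectra.append(Spectrum(
            mz, inten, kind=kind,
            precursor_mz=float(meta["precursormz"]) if "precursormz" in meta else None,
            rt=float(meta["retentiontime"]) if "retentiontime" in meta else None,
            name=meta.get("name", "")))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                _flush()
                meta, peaks, expecting = {}, [], 0
                continue
            if ":" in line and not line[0].isdigit():
                key, _, val = line.partition(":")
                meta[key.strip().lower()] = val.strip()
                if key.strip().lower() == "num peaks":
                    expecting = int(val)
            else:
                parts = line.replace(";", " ").split()
                if len(parts) < 2:
                    raise ValueError(f"malformed peak line: {line!r}")
                peaks.append((float(parts[0]), float(parts[1])))
    _flush()
    return spectra


def cosine_match(s1: Spectrum, s2: Spectrum, mz_tol: float = 0.01) -> float:
    """Normalized dot-product similarity over tolerance-matched peak pairs.

    Peaks of the two spectra are paired one-to-one within ``mz_tol`` Da by
    maximum-weight assignment on the intensity products; the score is the sum
    of matched products over the product of the spectrum norms, so a
    self-match scores exactly 1 and disjoint m/z sets score 0.
    """
    from scipy.optimize import linear_sum_assignment

    if s1.is_empty or s2.is_empty:
        raise ValueError("cosine match requires non-empty spectra")
    prod = np.outer(s1.intensity, s2.intensity)
    prod[np.abs(np.subtract.outer(s1.mz, s2.mz)) > mz_tol] = 0.0
    ri, cj = linear_sum_assignment(-prod)
    score = float(prod[ri, cj].sum())
    norm = float(np.linalg.norm(s1.intensity) * np.linalg.norm(s2.intensity))
    return score / norm if norm > 0 else 0.0
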