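"""MHC binding-affinity and cathepsin-cleavage scoring.

The scoring layer is pluggable: any callable mapping a peptide window to a
predicted ln IC50 (natural-log nanomolar) can serve as an ensemble member.
A deterministic physicochemical surrogate is shipped so that every
downstream computation — ensemble aggregation, within-protein Johnson Sb
standardization, threshold binding-fraction profiles, motif-conditioned
affinity distributions — is fully testable without external training data.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from tcemrep.motif_engine import (
    REGISTERS,
    CSO_FLANK,
    PeptideWindow,
    cleavage_site_octomer,
    enumerate_windows,
    extract_motif,
)
from tcemrep.sequence_io import RepertoireDataset, SequenceRecord

# ---------------------------------------------------------------------------
# Allele roster
# ---------------------------------------------------------------------------

#: Default HLA allele roster: 16 DR, 6 DP and 6 DQ class II predictors plus
#: the class I A and B alleles shipped with the default configuration.
DEFAULT_ALLELES: tuple[str, ...] = (
    # MHC class II DR (16)
    "DRB1*01:01", "DRB1*03:01", "DRB1*04:01", "DRB1*04:04", "DRB1*04:05",
    "DRB1*07:01", "DRB1*08:02", "DRB1*09:01", "DRB1*11:01", "DRB1*12:01",
    "DRB1*13:02", "DRB1*15:01", "DRB3*01:01", "DRB3*02:02", "DRB4*01:01",
    "DRB5*01:01",
    # MHC class II DP (6)
    "DPA1*01:03-DPB1*02:01", "DPA1*01:03-DPB1*04:02", "DPA1*01:03-DPB1*04:01",
    "DPA1*02:01-DPB1*01:01", "DPA1*02:01-DPB1*05:01", "DPA1*03:01-DPB1*04:02",
    # MHC class II DQ (6)
    "DQA1*01:01-DQB1*05:01", "DQA1*01:02-DQB1*06:02", "DQA1*03:01-DQB1*03:02",
    "DQA1*04:01-DQB1*04:02", "DQA1*05:01-DQB1*02:01", "DQA1*05:01-DQB1*03:01",
    # MHC class IA (20)
    "A*01:01", "A*02:01", "A*02:02", "A*02:03", "A*02:06", "A*03:01",
    "A*11:01", "A*23:01", "A*24:02", "A*24:03", "A*26:01", "A*29:02",
    "A*30:01", "A*30:02", "A*31:01", "A*32:01", "A*33:01", "A*68:01",
    "A*68:02", "A*69:01",
    # MHC class IB (16)
    "B*07:02", "B*08:01", "B*15:01", "B*15:03", "B*18:01", "B*27:05",
    "B*35:01", "B*40:01", "B*40:02", "B*44:02", "B*44:01", "B*51:01",
    "B*53:01", "B*54:01", "B*57:01", "B*58:01",
)

CLASS_II_PREFIXES = ("DRB", "DPA", "DQA")


def allele_mhc_class(allele_id: str) -> str:
    """``"II"`` for DR/DP/DQ identifiers, ``"I"`` otherwise."""
    return "II" if allele_id.startswith(CLASS_II_PREFIXES) else "I"


def default_window_length(allele_id: str) -> int:
    """15 for class II alleles, 9 for class I."""
    return 15 if allele_mhc_class(allele_id) == "II" else 9


def dr_alleles(roster: Sequence[str] = DEFAULT_ALLELES) -> list[str]:
    """The DR subset (identifiers beginning DRB) of a roster."""
    return [a for a in roster if a.startswith("DRB")]


# ---------------------------------------------------------------------------
# Physicochemical surrogate scoring
# ---------------------------------------------------------------------------

# Five standard per-residue indices: Kyte-Doolittle hydropathy, van der
# Waals volume (A^3), Grantham polarity, isoelectric point, and a
# normalized flexibility index.
_AA_PROPERTIES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (1.8, 88.6, 8.1, 6.00, 0.36),
    "C": (2.5, 108.5, 5.5, 5.07, 0.35),
    "D": (-3.5, 111.1, 13.0, 2.77, 0.51),
    "E": (-3.5, 138.4, 12.3, 3.22, 0.50),
    "F": (2.8, 189.9, 5.2, 5.48, 0.31),
    "G": (-0.4, 60.1, 9.0, 5.97, 0.54),
    "H": (-3.2, 153.2, 10.4, 7.59, 0.32),
    "I": (4.5, 166.7, 5.2, 6.02, 0.46),
    "K": (-3.9, 168.6, 11.3, 9.74, 0.47),
    "L": (3.8, 166.7, 4.9, 5.98, 0.37),
    "M": (1.9, 162.9, 5.7, 5.74, 0.30),
    "N": (-3.5, 114.1, 11.6, 5.41, 0.46),
    "P": (-1.6, 112.7, 8.0, 6.30, 0.51),
    "Q": (-3.5, 143.8, 10.5, 5.65, 0.49),
    "R": (-4.5, 173.4, 10.5, 10.76, 0.53),
    "S": (-0.8, 89.0, 9.2, 5.68, 0.51),
    "T": (-0.7, 116.1, 8.6, 5.60, 0.44),
    "V": (4.2, 140.0, 5.9, 5.96, 0.39),
    "W": (-0.9, 227.8, 5.4, 5.89, 0.31),
    "Y": (-1.3, 193.6, 6.2, 5.66, 0.42),
}

_PROP_MATRIX = np.array([_AA_PROPERTIES[a] for a in sorted(_AA_PROPERTIES)])
_PROP_MEAN = _PROP_MATRIX.mean(axis=0)
_PROP_SD = _PROP_MATRIX.std(axis=0)
_AA_INDEX = {a: i for i, a in enumerate(sorted(_AA_PROPERTIES))}
_PROP_Z = (_PROP_MATRIX - _PROP_MEAN) / _PROP_SD
_N_PROPS = _PROP_Z.shape[1]


def _peptide_features(residues: str) -> np.ndarray:
    """(length x n_properties) z-scored feature matrix for a peptide."""
    idx = [_AA_INDEX[a] for a in residues]
    return _PROP_Z[idx]


def _stable_entropy(*parts: int | str) -> list[int]:
    """Deterministic entropy words from mixed identifiers (process-stable,
    unlike builtin hash)."""
    out: list[int] = []
    for part in parts:
        if isinstance(part, str):
            out.append(zlib.crc32(part.encode()))
        else:
            out.append(int(part) & 0xFFFFFFFF)
    return out


@dataclass
class AffinityPredictor:
    """An ensemble of ln-IC50 scoring functions for one allele.

    Every member must accept a :class:`PeptideWindow` of ``window_length``
    residues and return a float ln IC50 in natural-log nanomolar units.
    """

    allele_id: str
    members: list[Callable[[PeptideWindow], float]]
    window_length: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("predictor needs at least one ensemble member")
        if self.window_length not in (9, 15):
            raise ValueError("window_length must be 9 or 15")


def ensemble_predict(
    predictor: AffinityPredictor, window: PeptideWindow
) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of member predictions."""
    if window.length != predictor.window_length:
        raise ValueError(
            f"window length {window.length} does not match predictor "
            f"{predictor.allele_id} (expects {predictor.window_length})"
        )
    scores = np.array([member(window) for member in predictor.members], dtype=float)
    sd = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    return float(np.mean(scores)), sd


def make_surrogate_affinity_predictor(
    allele_id: str,
    seed: int,
    members: int = 10,
    window_length: int | None = None,
) -> AffinityPredictor:
    """Deterministic surrogate ensemble for one allele.

    Each member scores a window as an affine function of the z-scored
    physicochemical indices of its residues, with position- and
    property-specific weights drawn reproducibly from (allele_id, seed,
    member index).  Members of one allele share most of their weight
    structure (an allele 'landscape') plus small member-specific
    perturbations, giving non-zero but modest ensemble SDs.  Output is
    centred near ln(500 nM) with SD around 1.5 ln units.
    """
    if members < 1:
        raise ValueError("members must be >= 1")
    if window_length is None:
        window_length = default_window_length(allele_id)

    base_rng = np.random.default_rng(_stable_entropy(allele_id, seed, "affinity"))
    allele_weights = base_rng.normal(0.0, 1.0, size=(window_length, _N_PROPS))
    scale = 1.5 / np.sqrt(window_length * _N_PROPS)

    member_fns: list[Callable[[PeptideWindow], float]] = []
    for m in range(members):
        m_rng = np.random.default_rng(_stable_entropy(allele_id, seed, "member", m))
        perturbation = m_rng.normal(0.0, 0.15, size=(window_length, _N_PROPS))
        weights = (allele_weights + perturbation) * scale
        offset = float(m_rng.normal(0.0, 0.05))

        def member(window: PeptideWindow, _w=weights, _b=offset) -> float:
            feats = _peptide_features(window.residues)
            return float(np.log(500.0) + (_w * feats).sum() + _b)

        member_fns.append(member)
    return AffinityPredictor(
        allele_id=allele_id, members=member_fns, window_length=window_length
    )


# ---------------------------------------------------------------------------
# Johnson Sb standardization
# ---------------------------------------------------------------------------


@dataclass
class JohnsonSbFit:
    """Fitted Johnson Sb transform z = gamma + delta * logit((x-xi)/lambda)."""

    gamma: float
    delta: float
    xi: float
    lam: float
    method: str  # "johnson_sb" or "zscore_fallback"

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.method == "zscore_fallback":
            return (np.asarray(values, dtype=float) - self.gamma) / self.delta
        u = (np.asarray(values, dtype=float) - self.xi) / self.lam
        u = np.clip(u, 1e-12, 1 - 1e-12)
        return self.gamma + self.delta * np.log(u / (1.0 - u))


def johnson_sb_standardize(
    values: Sequence[float] | np.ndarray, min_n: int = 20
) -> tuple[np.ndarray, JohnsonSbFit]:
    """Standardize one allele's ln IC50 values within one protein to zero
    mean and unit variance via a Johnson Sb transform.

    The four Sb parameters are estimated by maximum likelihood (bounds are
    then guaranteed to enclose the sample); the transformed values are
    affinely refined so the sample has exactly zero mean and unit sample
    SD, which keeps the transform strictly monotone and rank-preserving.
    If the likelihood fit fails, a quantile-matching fallback regresses
    normal scores on the logit of the sample scaled to bounds 1% of the
    range beyond the observed extremes.  Fewer than *min_n* values fall
    back to plain z-scoring with a warning; constant input raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if np.ptp(x) == 0:
        raise ValueError("constant input: Johnson Sb standardization is degenerate")
    if x.size < min_n:
        warnings.warn(
            f"only {x.size} values (< {min_n}); falling back to plain z-scoring",
            stacklevel=2,
        )
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        fit = JohnsonSbFit(gamma=mu, delta=sd, xi=np.nan, lam=np.nan, method="zscore_fallback")
        return fit.transform(x), fit

    xi = lam = gamma0 = delta0 = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gamma0, delta0, xi, lam = stats.johnsonsb.fit(x)
        if not (xi < np.min(x) and xi + lam > np.max(x) and delta0 > 0):
            xi = None  # degenerate fit; use quantile fallback
    except Exception:
        xi = None

    if xi is None:
        rng_width = float(np.ptp(x))
        xi = float(np.min(x)) - 0.01 * rng_width
        lam = rng_width * 1.02
        u = (x - xi) / lam
        y = np.log(u / (1.0 - u))
        # quantile matching: regress Blom normal scores of the ranks on y
        order = np.argsort(y)
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, x.size + 1)
        normal_scores = stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
        delta0, gamma0, *_ = stats.linregress(y, normal_scores)
    else:
        u = np.clip((x - xi) / lam, 1e-12, 1 - 1e-12)
        y = np.log(u / (1.0 - u))

    z0 = gamma0 + delta0 * y
    # affine refinement to exact zero mean / unit sample SD (order-preserving)
    mu0, sd0 = float(np.mean(z0)), float(np.std(z0, ddof=1))
    z = (z0 - mu0) / sd0
    delta = float(delta0 / sd0)
    gamma = float((gamma0 - mu0) / sd0)
    fit = JohnsonSbFit(gamma=gamma, delta=delta, xi=float(xi), lam=float(lam), method="johnson_sb")
    return z, fit


# ---------------------------------------------------------------------------
# Affinity matrices and binding profiles
# ---------------------------------------------------------------------------


@dataclass
class AffinityMatrix:
    """Per (peptide window x allele) ensemble predictions for one protein.

    ``mean_ln_ic50`` and ``ensemble_sd`` are (n_windows x n_alleles)
    arrays; ``standardized`` holds the within-protein Johnson Sb z-scores
    computed per allele column.
    """

    parent_id: str
    windows: list[PeptideWindow]
    alleles: list[str]
    mean_ln_ic50: np.ndarray
    ensemble_sd: np.ndarray
    standardized: np.ndarray | None = None
    sb_fits: dict[str, JohnsonSbFit] = field(default_factory=dict)

    def standardize(self) -> "AffinityMatrix":
        """Johnson-Sb-standardize each allele column within this protein."""
        z = np.empty_like(self.mean_ln_ic50)
        for j, allele in enumerate(self.alleles):
            z[:, j], fit = johnson_sb_standardize(self.mean_ln_ic50[:, j])
            self.sb_fits[allele] = fit
        self.standardized = z
        return self

    def column(self, allele_id: str, standardized: bool = True) -> np.ndarray:
        j = self.alleles.index(allele_id)
        if standardized:
            if self.standardized is None:
                raise ValueError("matrix not standardized; call standardize() first")
            return self.standardized[:, j]
        return self.mean_ln_ic50[:, j]


def score_protein(
    record: SequenceRecord,
    predictors: Sequence[AffinityPredictor],
    standardize: bool = True,
) -> AffinityMatrix:
    """Score every non-skipped window of *record* with each predictor.

    All predictors must share one window length (class I and class II
    runs are separate matrices).
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    lengths = {p.window_length for p in predictors}
    if len(lengths) > 1:
        raise ValueError(f"predictors mix window lengths {sorted(lengths)}")
    k = lengths.pop()
    windows = [w for w in enumerate_windows(record, k) if not w.skip]
    if not windows:
        raise ValueError(f"record {record.id!r} yields no scoreable {k}-mer windows")
    mean = np.empty((len(windows), len(predictors)))
    sd = np.empty_like(mean)
    for j, predictor in enumerate(predictors):
        for i, window in enumerate(windows):
            mean[i, j], sd[i, j] = ensemble_predict(predictor, window)
    matrix = AffinityMatrix(
        parent_id=record.id,
        windows=windows,
        alleles=[p.allele_id for p in predictors],
        mean_ln_ic50=mean,
        ensemble_sd=sd,
    )
    if standardize:
        matrix.standardize()
    return matrix


@dataclass
class BindingProfile:
    """Per-position fraction of alleles binding more strongly than the
    within-protein threshold (standardized ln IC50 < -threshold_sd)."""

    parent_id: str
    positions: np.ndarray  # window-centre positions, 1-based
    fractions: np.ndarray  # in [0, 1]
    threshold_sd: float
    alleles: list[str]


def binding_fraction_profile(
    matrix: AffinityMatrix,
    allele_group: Sequence[str] | None = None,
    threshold_sd: float = 1.0,
    scale: str = "standardized",
) -> BindingProfile:
    """Fraction of group alleles whose affinity for each window is more
    than *threshold_sd* SD below that allele's within-protein mean.

    Lower ln IC50 means stronger binding, so the threshold is a
    standardized value below ``-threshold_sd``.  ``scale='raw'`` applies
    the same rule to mean-centred, SD-scaled raw ln IC50 instead of the
    Johnson Sb z-scores.
    """
    alleles = list(allele_group) if allele_group is not None else list(matrix.alleles)
    if not alleles:
        raise ValueError("allele group must be non-empty")
    missing = set(alleles) - set(matrix.alleles)
    if missing:
        raise ValueError(f"alleles not in matrix: {sorted(missing)}")
    cols = [matrix.alleles.index(a) for a in alleles]
    if scale == "standardized":
        if matrix.standardized is None:
            raise ValueError("matrix not standardized; call standardize() first")
        z = matrix.standardized[:, cols]
    elif scale == "raw":
        raw = matrix.mean_ln_ic50[:, cols]
        z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    below = (z < -threshold_sd).sum(axis=1)
    k = matrix.windows[0].length
    centers = np.array([w.start + k // 2 for w in matrix.windows])
    return BindingProfile(
        parent_id=matrix.parent_id,
        positions=centers,
        fractions=below / len(alleles),
        threshold_sd=threshold_sd,
        alleles=alleles,
    )


def aggregate_binding_profiles(profiles: Sequence[BindingProfile]):
    """Aggregate per-record profiles over a repertoire aligned on position.

    Returns a DataFrame with columns position, mean_fraction, p10, p90.
    """
    import pandas as pd

    if not profiles:
        raise ValueError("no profiles to aggregate")
    by_position: dict[int, list[float]] = {}
    for profile in profiles:
        for pos, frac in zip(profile.positions, profile.fractions):
            by_position.setdefault(int(pos), []).append(float(frac))
    rows = []
    for pos in sorted(by_position):
        vals = np.array(by_position[pos])
        rows.append(
            (pos, float(vals.mean()), float(np.percentile(vals, 10)),
             float(np.percentile(vals, 90)))
        )
    return pd.DataFrame(rows, columns=["position", "mean_fraction", "p10", "p90"])


# ---------------------------------------------------------------------------
# Cathepsin cleavage
# ---------------------------------------------------------------------------

CATHEPSINS = ("cathepsin_B", "cathepsin_L", "cathepsin_S")


@dataclass
class CleavagePredictor:
    """Octamer cleavage-probability scorer for one endosomal cathepsin.

    ``models`` maps the central P1P1' dipeptide to a scoring function on
    the full octamer returning a probability in [0, 1]; a default model is
    used for dipeptides without a dedicated entry.
    """

    enzyme: str
    models: Mapping[str, Callable[[PeptideWindow], float]]
    default_model: Callable[[PeptideWindow], float]

    def __post_init__(self) -> None:
        if self.enzyme not in CATHEPSINS:
            raise ValueError(f"enzyme must be one of {CATHEPSINS}, got {self.enzyme!r}")

    def score(self, octamer: PeptideWindow) -> float:
        if octamer.length != 8:
            raise ValueError(f"cleavage scoring expects an octamer, got {octamer.length}")
        dipeptide = octamer.residues[3:5]  # P1 P1'
        model = self.models.get(dipeptide, self.default_model)
        p = float(model(octamer))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"cleavage model returned {p} outside [0, 1]")
        return p


def make_surrogate_cleavage_predictor(enzyme: str, seed: int) -> CleavagePredictor:
    """Deterministic surrogate cathepsin model.

    Each P1P1' dipeptide gets its own logistic scoring function of the
    octamer's physicochemical features, emulating per-dipeptide ensembles.
    """
    def make_model(dipeptide_key: str) -> Callable[[PeptideWindow], float]:
        rng = np.random.default_rng(_stable_entropy(enzyme, seed, dipeptide_key))
        weights = rng.normal(0.0, 1.0, size=(8, _N_PROPS)) / np.sqrt(8 * _N_PROPS)
        bias = float(rng.normal(0.0, 0.5))

        def model(octamer: PeptideWindow) -> float:
            feats = _peptide_features(octamer.residues)
            return float(1.0 / (1.0 + np.exp(-((weights * feats).sum() * 3.0 + bias))))

        return model

    from tcemrep.sequence_io import AA20

    models = {a + b: make_model(a + b) for a in AA20 for b in AA20}
    return CleavagePredictor(
        enzyme=enzyme, models=models, default_model=make_model("__default__")
    )


def cleavage_profile(
    predictor: CleavagePredictor, record: SequenceRecord
) -> dict[int, float]:
    """Cleavage probability per interior scissile bond.

    Bond *b* is the bond after residue *b*; bonds 4 .. L-4 are scored from
    the octamer centred on them, bonds nearer the termini are absent.
    Octamers containing X are skipped.
    """
    L = len(record)
    if L < 8:
        warnings.warn(
            f"record {record.id!r} length {L} < 8; empty cleavage profile",
            stacklevel=2,
        )
        return {}
    profile: dict[int, float] = {}
    for bond in range(CSO_FLANK, L - CSO_FLANK + 1):
        octamer = cleavage_site_octomer(record, bond)
        if octamer.skip:
            continue
        profile[bond] = predictor.score(octamer)
    return profile


# ---------------------------------------------------------------------------
# Motif-conditioned affinity distributions
# ---------------------------------------------------------------------------


def affinity_distribution_by_motif(
    dataset: RepertoireDataset,
    motif,
    matrix_provider: Callable[[SequenceRecord], AffinityMatrix],
) -> dict[str, np.ndarray]:
    """Standardized affinities, per allele, of every window carrying *motif*.

    *motif* is a :class:`~tcemrep.motif_engine.Motif` (or anything with
    ``register`` and ``letters``) in a TCEM register; *matrix_provider*
    maps a record to its standardized :class:`AffinityMatrix` for the
    register's window length.  Returns allele -> array of z-scores over
    all matching windows in the dataset; empty with a warning if the motif
    never occurs.
    """
    register = REGISTERS[motif.register]
    if not motif.register.startswith("TCEM"):
        raise ValueError("affinity distributions are motif-conditioned on TCEM registers")
    collected: dict[str, list[float]] = {}
    n_windows = 0
    for rec in dataset:
        matching: list[int] = []
        matrix = None
        for window in enumerate_windows(rec, register.window_length):
            if window.skip:
                continue
            if extract_motif(window, register).letters == motif.letters:
                if matrix is None:
                    matrix = matrix_provider(rec)
                    if matrix.standardized is None:
                        matrix.standardize()
                    index_by_start = {w.start: i for i, w in enumerate(matrix.windows)}
                matching.append(index_by_start[window.start])
        if matrix is None:
            continue
        n_windows += len(matching)
        for j, allele in enumerate(matrix.alleles):
            collected.setdefault(allele, []).extend(
                float(matrix.standardized[i, j]) for i in matching
            )
    if n_windows == 0:
        warnings.warn(
            f"motif {motif.letters!r} ({motif.register}) absent from dataset",
            stacklevel=2,
        )
        return {}
    return {allele: np.array(vals) for allele, vals in collected.items()}


def summarize_distributions(
    distributions: Mapping[str, np.ndarray],
    quantiles: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
):
    """Per-allele summary quantiles of motif-conditioned distributions."""
    import pandas as pd

    rows = []
    for allele, vals in distributions.items():
        rows.append(
            [allele, len(vals), float(np.mean(vals))]
            + [float(np.quantile(vals, q)) for q in quantiles]
        )
    return pd.DataFrame(
        rows, columns=["allele", "n", "mean"] + [f"q{int(q * 100)}" for q in quantiles]
    )
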