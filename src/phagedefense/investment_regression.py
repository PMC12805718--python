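"""Genomic defense-investment quantification and power-law regression.

For each genome the investments ``I_PCD`` and ``I_Imm`` are the fractions of
the genome length (in nucleotides) occupied by PCD-class and immunity-class
defense systems.  Across species the two investments follow

    I_PCD = beta * I_Imm ** alpha,

with multiplicative lognormal noise of log-scale standard deviation gamma.
Because the noise is lognormal, maximum likelihood for (alpha, beta) is
exactly ordinary least squares on log-log coordinates, with the ML variance
``gamma^2`` the mean squared residual; fixing alpha (the "naive" linear
alpha=1 and flat alpha=0 references) leaves closed forms for beta and gamma.
Model comparison uses BIC = k*ln(n) - 2*loglik.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DefenseSystemMap",
    "GenomeRecord",
    "PowerLawFit",
    "compute_investment",
    "records_from_annotations",
    "fit_power_law",
    "compare_bic",
    "predictive_band",
]

_CLASSES = ("PCD", "immunity", "undefined")

#: Minimal classification derived from the functional descriptions of the
#: major system families: recognition/targeting systems are immunity,
#: dormancy/suicide systems are PCD.  Real analyses should supply a full map.
DEFAULT_CLASSIFICATION = {
    "CRISPR-Cas": "immunity",
    "Restriction-Modification": "immunity",
    "BREX": "immunity",
    "DISARM": "immunity",
    "DNA_phosphorothioation": "immunity",
    "Toxin-Antitoxin": "PCD",
    "Abortive_infection": "PCD",
    "CBASS": "PCD",
}


class DefenseSystemMap:
    """Mapping from defense-system name to class (PCD/immunity/undefined)."""

    def __init__(self, mapping: Mapping[str, str],
                 unknown_policy: str = "undefined"):
        for name, cls in mapping.items():
            if cls not in _CLASSES:
                raise ValueError(f"system {name!r} has unknown class {cls!r}")
        if unknown_policy not in ("undefined", "error"):
            raise ValueError("unknown_policy must be 'undefined' or 'error'")
        self._map = dict(mapping)
        self.unknown_policy = unknown_policy
        self._warned: set = set()

    @classmethod
    def default(cls) -> "DefenseSystemMap":
        return cls(DEFAULT_CLASSIFICATION)

    @classmethod
    def from_tsv(cls, path, **kw) -> "DefenseSystemMap":
        df = pd.read_csv(path, sep="\t")
        if not {"system_name", "class"} <= set(df.columns):
            raise ValueError("classification map needs columns system_name, class")
        return cls(dict(zip(df["system_name"], df["class"])), **kw)

    def classify(self, system: str) -> str:
        cls = self._map.get(system)
        if cls is None:
            if self.unknown_policy == "error":
                raise KeyError(f"unknown defense system {system!r}")
            if system not in self._warned:
                warnings.warn(f"system {system!r} not in classification map; "
                              "treated as undefined", stacklevel=2)
                self._warned.add(system)
            return "undefined"
        return cls

    def counts(self) -> dict:
        out = {c: 0 for c in _CLASSES}
        for cls in self._map.values():
            out[cls] += 1
        return out

    def __len__(self):
        return len(self._map)


@dataclass
class GenomeRecord:
    species_id: str
    genome_length: int
    pcd_nt: int
    imm_nt: int

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.pcd_nt < 0 or self.imm_nt < 0:
            raise ValueError("defense nucleotide counts must be non-negative")
        if self.pcd_nt + self.imm_nt > self.genome_length:
            raise ValueError("defense nucleotides exceed genome length")

    @property
    def I_PCD(self) -> float:
        return self.pcd_nt / self.genome_length

    @property
    def I_Imm(self) -> float:
        return self.imm_nt / self.genome_length


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def compute_investment(
    genes: pd.DataFrame,
    system_map: DefenseSystemMap,
    genome_length: int,
    species_id: str = "",
) -> GenomeRecord:
    """Aggregate one genome's defense genes into a :class:`GenomeRecord`.

    ``genes`` carries one row per defense gene with a ``system_name`` column
    and either a ``gene_length`` column or 0-based half-open coordinates
    (``contig``, ``start``, ``end``).  With coordinates, overlapping genes of
    the same class are counted once (interval union); with plain lengths the
    caller asserts the genes do not overlap.  Undefined-class systems
    contribute to neither investment.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    nts = {"PCD": 0, "immunity": 0}
    has_coords = {"start", "end"}.issubset(genes.columns)
    if has_coords:
        by_class: dict = {"PCD": {}, "immunity": {}}
        for row in genes.itertuples(index=False):
            cls = system_map.classify(row.system_name)
            if cls == "undefined":
                continue
            s, e = int(row.start), int(row.end)
            if not 0 <= s < e:
                raise ValueError(f"bad interval [{s}, {e})")
            contig = getattr(row, "contig", "")
            by_class[cls].setdefault(contig, []).append((s, e))
        for cls, contigs in by_class.items():
            nts[cls] = sum(_union_length(iv) for iv in contigs.values())
    else:
        if "gene_length" not in genes.columns:
            raise ValueError("genes need either gene_length or start/end columns")
        for row in genes.itertuples(index=False):
            cls = system_map.classify(row.system_name)
            if cls == "undefined":
                continue
            L = int(row.gene_length)
            if L <= 0:
                raise ValueError(f"gene of non-positive length {L}")
            nts[cls] += L
    return GenomeRecord(species_id=species_id, genome_length=int(genome_length),
                        pcd_nt=nts["PCD"], imm_nt=nts["immunity"])


def records_from_annotations(
    annotations: pd.DataFrame, system_map: DefenseSystemMap
) -> list[GenomeRecord]:
    """Build one record per species from a long-format annotation table
    (columns: species_id, genome_length, system_name, and gene_length or
    start/end)."""
    out = []
    for (sp, gl), grp in annotations.groupby(["species_id", "genome_length"],
                                             sort=True):
        out.append(compute_investment(grp, system_map, int(gl), species_id=str(sp)))
    return out


@dataclass
class PowerLawFit:
    alpha: float
    beta: float
    gamma: float
    n: int
    loglik: float
    bic: float
    alpha_fixed: bool
    n_excluded_zero: int = 0
    _fingerprint: float = field(default=0.0, repr=False)

    @property
    def k_params(self) -> int:
        return 2 if self.alpha_fixed else 3


_GAMMA_FLOOR = 1e-12


def _prepare_xy(records: Sequence[GenomeRecord]):
    ip = np.array([r.I_PCD for r in records])
    ii = np.array([r.I_Imm for r in records])
    pos = (ip > 0) & (ii > 0)
    return np.log(ii[pos]), np.log(ip[pos]), int((~pos).sum())


def fit_power_law(
    records: Sequence[GenomeRecord],
    fixed_alpha: Optional[float] = None,
) -> PowerLawFit:
    """Maximum-likelihood fit of ``I_PCD = beta * I_Imm**alpha`` with
    lognormal noise.

    Records with a zero investment on either axis are excluded (the
    lognormal has positive support); their count is reported.  The
    log-likelihood is that of the observed ``I_PCD`` values under the
    lognormal predictive density, so fits with different ``fixed_alpha`` on
    the same records are directly comparable by BIC.
    """
    x, y, n_zero = _prepare_xy(records)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 records with positive investments")
    if fixed_alpha is None:
        if np.ptp(x) == 0:
            raise ValueError("all I_Imm equal: alpha is unidentifiable "
                             "(rank-deficient design)")
        alpha, logbeta = np.polyfit(x, y, 1)
        k = 3
        alpha_fixed = False
    else:
        alpha = float(fixed_alpha)
        logbeta = float(np.mean(y - alpha * x))
        k = 2
        alpha_fixed = True
    resid = y - (logbeta + alpha * x)
    gamma2 = float(np.mean(resid**2))
    gamma = max(np.sqrt(gamma2), _GAMMA_FLOOR)
    # lognormal density of I_PCD: Normal density of log I_PCD minus sum(log I_PCD)
    loglik = float(-0.5 * n * np.log(2 * np.pi * gamma**2)
                   - np.sum(resid**2) / (2 * gamma**2) - np.sum(y))
    bic = k * np.log(n) - 2 * loglik
    return PowerLawFit(alpha=float(alpha), beta=float(np.exp(logbeta)),
                       gamma=float(gamma), n=n, loglik=loglik, bic=float(bic),
                       alpha_fixed=alpha_fixed, n_excluded_zero=n_zero,
                       _fingerprint=float(np.sum(x) + np.sum(y)))


def compare_bic(fit_free: PowerLawFit, *fixed_fits: PowerLawFit,
                strong_evidence: float = 10.0) -> pd.DataFrame:
    """Tabulate BIC differences of fixed-alpha fits relative to the free fit.

    All fits must be computed on the identical record subset.  Positive
    ``delta_bic`` means the free (ML) model is preferred; differences above
    ``strong_evidence`` are flagged as strong.
    """
    fits = (fit_free,) + fixed_fits
    for f in fits[1:]:
        if f.n != fit_free.n or not np.isclose(f._fingerprint,
                                               fit_free._fingerprint):
            raise ValueError("fits were computed on different record subsets")
    rows = []
    for f in fits:
        d = f.bic - fit_free.bic
        rows.append(dict(
            alpha=f.alpha, alpha_fixed=f.alpha_fixed, bic=f.bic,
            delta_bic=d, strong=bool(d > strong_evidence)))
    df = pd.DataFrame(rows)
    df["preferred"] = df["bic"] == df["bic"].min()
    return df


def predictive_band(
    fit: PowerLawFit,
    I_Imm: Sequence[float],
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Lognormal predictive quantiles of I_PCD at the given I_Imm values.

    The 50% quantile is the median curve ``beta * I_Imm**alpha``; as gamma
    approaches zero every quantile collapses onto it.
    """
    from scipy.stats import norm

    x = np.asarray(I_Imm, dtype=float)
    if np.any(x <= 0):
        raise ValueError("I_Imm values must be positive")
    out = {"I_Imm": x}
    mu = np.log(fit.beta) + fit.alpha * np.log(x)
    for qt in quantiles:
        z = norm.ppf(qt)
        out[f"q{qt:g}"] = np.exp(mu + fit.gamma * z)
    return pd.DataFrame(out)
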