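"""Seeded generators for every input the analysis pipelines consume.

The generators emulate the two empirical data types the statistics modules
operate on — per-genome defense-system annotation tables and gut-metagenome
relative-abundance profiles — under fully known ground truth: investments
follow the lognormal power law by construction, abundance tiers and the
PCD-investment shift between them are planted, and system panels carry
recorded quadrant memberships.  All generators are pure functions of their
spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .investment_regression import DefenseSystemMap, GenomeRecord
from .params import EcologyParams, StrategyParams

__all__ = [
    "SynthGenomeSpec",
    "SynthGutSpec",
    "gen_defense_genomes",
    "gen_gut_dataset",
    "gen_system_panel",
    "fixture_ecologies",
    "synthetic_system_map",
]

# Small synthetic catalogues of system names per class.  PCD systems are
# built from shorter genes than immunity systems, reflecting the observation
# that PCD modules comprise substantially fewer nucleotides.
_PCD_SYSTEMS = ["Toxin-Antitoxin", "Abortive_infection", "CBASS",
                "AbiE", "AbiQ", "Retron", "PifA", "Lit", "PrrC", "RexAB"]
_IMM_SYSTEMS = ["CRISPR-Cas", "Restriction-Modification", "BREX", "DISARM",
                "DNA_phosphorothioation", "Gabija", "Druantia", "Septu"]
_UNDEF_SYSTEMS = ["Wadjet", "Zorya", "Dodola"]


def synthetic_system_map() -> DefenseSystemMap:
    m = {s: "PCD" for s in _PCD_SYSTEMS}
    m.update({s: "immunity" for s in _IMM_SYSTEMS})
    m.update({s: "undefined" for s in _UNDEF_SYSTEMS})
    return DefenseSystemMap(m)


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Generator spec for power-law-distributed defense investments.

    Defaults reproduce the study conditions of the regression analysis:
    5121 species and a sublinear exponent alpha = 0.554.  beta and gamma
    are nominal calibration constants chosen so that investments span
    realistic genome fractions (immunity around 1% of the genome, PCD a few
    tenths of a percent, scatter under one order of magnitude).
    """

    n_species: int = 5121
    alpha: float = 0.554
    beta: float = 0.05
    gamma: float = 0.8
    mu_log_imm: float = float(np.log(0.01))  # centre of log I_Imm
    sd_log_imm: float = 0.8
    mu_log_genome: float = float(np.log(3.5e6))  # nt
    sd_log_genome: float = 0.35
    pcd_gene_len: float = 900.0  # lognormal medians, nt
    imm_gene_len: float = 2000.0
    gene_len_sd: float = 0.5
    seed: int = 0


def _emit_genes(rng, target_nt: int, names: list[str], median_len: float,
                sd: float) -> list[tuple[str, int]]:
    """Gene records whose lengths sum exactly to target_nt (the last gene is
    truncated to fit; genes are at least 50 nt)."""
    out = []
    remaining = int(target_nt)
    while remaining > 0:
        L = int(max(50, rng.lognormal(np.log(median_len), sd)))
        L = min(L, remaining)
        if remaining - L < 50:
            L = remaining
        out.append((names[int(rng.integers(len(names)))], L))
        remaining -= L
    return out


def gen_defense_genomes(spec: SynthGenomeSpec, emit_genes: bool = True):
    """Generate an annotation table whose investments follow the power law.

    Returns ``(annotations, records, truth)``: a long-format gene table
    (species_id, genome_length, gene_id, system_name, gene_length), the
    per-species :class:`GenomeRecord` list it aggregates to, and a truth
    DataFrame carrying the drawn (I_Imm, I_PCD) pairs and the generating
    (alpha, beta, gamma).  With ``emit_genes=False`` the gene-level table is
    skipped (annotations is None); the records are identical either way.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    L = np.rint(rng.lognormal(spec.mu_log_genome, spec.sd_log_genome, n)).astype(int)
    log_imm = rng.normal(spec.mu_log_imm, spec.sd_log_imm, n)
    noise = rng.normal(0.0, spec.gamma, n)
    log_pcd = np.log(spec.beta) + spec.alpha * log_imm + noise
    I_imm = np.exp(log_imm)
    I_pcd = np.exp(log_pcd)
    # keep total defense fraction physical
    cap = 0.25
    tot = I_imm + I_pcd
    over = tot > cap
    I_imm[over] *= cap / tot[over]
    I_pcd[over] *= cap / tot[over]
    rows = []
    records = []
    for i in range(n):
        sp = f"S{i:05d}"
        imm_nt = int(np.rint(I_imm[i] * L[i]))
        pcd_nt = int(np.rint(I_pcd[i] * L[i]))
        if emit_genes:
            genes = [(nm, gl, "PCD") for nm, gl in _emit_genes(
                rng, pcd_nt, _PCD_SYSTEMS, spec.pcd_gene_len, spec.gene_len_sd)]
            genes += [(nm, gl, "immunity") for nm, gl in _emit_genes(
                rng, imm_nt, _IMM_SYSTEMS, spec.imm_gene_len, spec.gene_len_sd)]
            # a few undefined-class distractor genes
            for _ in range(int(rng.integers(0, 3))):
                nm = _UNDEF_SYSTEMS[int(rng.integers(len(_UNDEF_SYSTEMS)))]
                genes.append((nm, int(rng.lognormal(np.log(1200), 0.4)),
                              "undefined"))
            for gi, (nm, gl, _cls) in enumerate(genes):
                rows.append((sp, int(L[i]), f"{sp}_g{gi:04d}", nm, int(gl)))
        records.append(GenomeRecord(species_id=sp, genome_length=int(L[i]),
                                    pcd_nt=pcd_nt, imm_nt=imm_nt))
    annotations = pd.DataFrame(
        rows, columns=["species_id", "genome_length", "gene_id",
                       "system_name", "gene_length"]) if emit_genes else None
    truth = pd.DataFrame(dict(
        species_id=[f"S{i:05d}" for i in range(n)],
        genome_length=L, I_Imm=I_imm, I_PCD=I_pcd))
    truth.attrs.update(alpha=spec.alpha, beta=spec.beta, gamma=spec.gamma)
    return annotations, records, truth


@dataclass(frozen=True)
class SynthGutSpec:
    """Generator spec for a gut-microbiome panel with planted abundance tiers.

    Three habitual tiers of species (high / mid / low mean abundance, plus a
    handful of rare species that fail the presence filter) give cleanly
    separated rank-abundance distributions.  The planted effect inflates the
    PCD investment of habitual high-tier species by ``delta`` on the log
    scale, leaving immunity untouched; ``genome_confound`` optionally gives
    high-tier species systematically larger genomes.
    """

    n_samples: int = 1000
    n_species: int = 150
    n_high: int = 30
    n_low: int = 45
    n_rare: int = 10
    delta: float = 1.0  # planted log-scale PCD shift of the high tier
    #: across-sample log-abundance noise; intermediate species additionally
    #: switch between a high and a low abundance state from sample to sample
    noise_stable: float = 0.35
    tier_spread: float = 0.3
    genome_confound: bool = False
    genomes_available: float = 0.85  # share of species with a genome
    seed: int = 0


def gen_gut_dataset(spec: SynthGutSpec):
    """Generate abundance profiles plus matching genome annotations.

    Returns ``(abundance, annotations, truth)``: a long abundance table
    (sample_id, species_id, relative_abundance), the defense-gene annotation
    table restricted to species with available genomes, and a truth frame
    with tier labels, planted investments and genome availability.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    n_mid = n - spec.n_high - spec.n_low - spec.n_rare
    if n_mid <= 0:
        raise ValueError("tier sizes exceed n_species")
    tiers = (["high"] * spec.n_high + ["mid"] * n_mid
             + ["low"] * spec.n_low + ["rare"] * spec.n_rare)
    mu = {"high": np.log(2e-2), "mid": np.log(1e-3),
          "low": np.log(5e-5), "rare": np.log(1e-5)}
    present_p = {"high": 1.0, "mid": 0.97, "low": 0.92, "rare": 0.05}
    species = [f"S{i:05d}" for i in range(n)]
    base = np.array([rng.normal(mu[t], spec.tier_spread) for t in tiers])
    sd = np.full(n, spec.noise_stable)
    is_mid = np.array([t == "mid" for t in tiers])
    # intermediate species are highly variable across individuals: their
    # abundance switches between a high and a low state from sample to
    # sample, so their rank quartiles straddle any threshold separating the
    # stable tiers and the classifier discards them
    mid_w = rng.uniform(0.3, 0.7, n)  # per-species probability of the high state
    # in the high state an intermediate species is statistically
    # indistinguishable from a habitual high-abundance species, and likewise
    # in the low state, so its rank quartiles straddle the block boundary
    mid_hi = rng.normal(mu["high"], spec.tier_spread, n)
    mid_lo = rng.normal(mu["low"], spec.tier_spread, n)

    # genome side: investments from the power-law generator
    gspec = SynthGenomeSpec(n_species=n, seed=int(rng.integers(2**31 - 1)))
    ann, records, gtruth = gen_defense_genomes(gspec)
    # plant the PCD effect: habitual high-tier species invest more in PCD
    shift = np.array([spec.delta if t == "high" else 0.0 for t in tiers])
    L = gtruth["genome_length"].to_numpy().astype(float)
    if spec.genome_confound:
        L = np.where(np.array(tiers) == "high", L * 1.6, L)
    pcd_nt = np.minimum(
        np.rint(gtruth["I_PCD"].to_numpy() * np.exp(shift) * L), 0.4 * L
    ).astype(int)
    imm_nt = np.rint(gtruth["I_Imm"].to_numpy() * L).astype(int)
    has_genome = rng.random(n) < spec.genomes_available
    records = [GenomeRecord(species_id=species[i], genome_length=int(L[i]),
                            pcd_nt=int(pcd_nt[i]), imm_nt=int(imm_nt[i]))
               for i in range(n) if has_genome[i]]
    # rebuild the annotation table consistent with the planted investments
    rows = []
    for rec in records:
        genes = [(nm, gl) for nm, gl in _emit_genes(
            rng, rec.pcd_nt, _PCD_SYSTEMS, gspec.pcd_gene_len, gspec.gene_len_sd)]
        genes += [(nm, gl) for nm, gl in _emit_genes(
            rng, rec.imm_nt, _IMM_SYSTEMS, gspec.imm_gene_len, gspec.gene_len_sd)]
        for gi, (nm, gl) in enumerate(genes):
            rows.append((rec.species_id, rec.genome_length,
                         f"{rec.species_id}_g{gi:04d}", nm, int(gl)))
    annotations = pd.DataFrame(
        rows, columns=["species_id", "genome_length", "gene_id",
                       "system_name", "gene_length"])

    # abundance side
    arows = []
    for s in range(spec.n_samples):
        sid = f"samp{s:04d}"
        present = rng.random(n) < np.array([present_p[t] for t in tiers])
        if not present.any():
            continue
        centre = np.where(is_mid & (rng.random(n) < mid_w), mid_hi,
                          np.where(is_mid, mid_lo, base))
        ab = np.where(present, np.exp(centre + sd * rng.normal(0, 1, n)), 0.0)
        ab = ab / ab.sum()
        for i in np.where(present)[0]:
            arows.append((sid, species[i], ab[i]))
    abundance = pd.DataFrame(
        arows, columns=["sample_id", "species_id", "relative_abundance"])
    truth = pd.DataFrame(dict(
        species_id=species, tier=tiers, base_log_abundance=base,
        genome_length=L.astype(int), pcd_nt=pcd_nt, imm_nt=imm_nt,
        has_genome=has_genome))
    truth.attrs.update(delta=spec.delta, records=records)
    return abundance, annotations, truth


# Paper-style quadrant composition of the synthetic pathway panel: counts of
# (low-group sign, high-group sign) classes among the 61 pathway profiles.
_PANEL_QUADRANTS = (("high-high", 5), ("low-high", 10),
                    ("low-low", 25), ("high-low", 21))


def gen_system_panel(
    genomes: pd.DataFrame,
    high_ids,
    low_ids,
    n_pathways: int = 61,
    random_set_size: int = 159,
    shift: float = 0.8,
    noise: float = 0.3,
    seed: int = 0,
):
    """Per-species nucleotide totals for a panel of functional systems.

    Builds ``n_pathways`` pathway-like profiles with planted quadrant
    memberships (log-nt shifts of +/- ``shift`` applied to the high- and
    low-abundant species groups), one PCD-like profile planted ``low-high``
    (overinvested in high-abundant, underinvested in low-abundant species)
    and one null "random gene collection" profile of ``random_set_size``
    families with no group structure — 63 systems in total.

    Returns ``(profiles, truth)``: a long DataFrame (species_id, system_id,
    total_nt) and a DataFrame of planted quadrants (the random profile's
    quadrant is recorded as ``null``).
    """
    rng = np.random.default_rng(seed)
    need = {"species_id", "genome_length"}
    if not need <= set(genomes.columns):
        raise ValueError(f"genomes table needs columns {sorted(need)}")
    sp = genomes["species_id"].astype(str).to_numpy()
    logL = np.log(genomes["genome_length"].to_numpy(dtype=float))
    high = np.isin(sp, [str(s) for s in high_ids])
    low = np.isin(sp, [str(s) for s in low_ids])

    quads = []
    for name, count in _PANEL_QUADRANTS:
        quads += [name] * count
    if len(quads) < n_pathways:
        quads += ["low-low"] * (n_pathways - len(quads))
    quads = quads[:n_pathways]

    def profile(quadrant: Optional[str], scale: float) -> np.ndarray:
        base = np.log(scale) + 1.0 * logL + rng.normal(0, noise, len(sp))
        if quadrant is not None:
            w_low, w_high = quadrant.split("-")
            base = base + np.where(high, shift if w_high == "high" else -shift, 0.0)
            base = base + np.where(low, shift if w_low == "high" else -shift, 0.0)
        return np.rint(np.exp(base)).astype(int)

    rows = []
    truth_rows = []
    for k, quad in enumerate(quads):
        name = f"COG_pathway_{k:02d}"
        nt = profile(quad, scale=2e-3)
        rows += list(zip(sp, [name] * len(sp), nt))
        truth_rows.append((name, quad))
    nt = profile("low-high", scale=3e-3)
    rows += list(zip(sp, ["PCD"] * len(sp), nt))
    truth_rows.append(("PCD", "low-high"))
    # the random profile emulates a bag of random_set_size unrelated gene
    # families: investment tracks genome size with no group structure
    nt = profile(None, scale=random_set_size * 1e-5)
    rows += list(zip(sp, ["random_genes"] * len(sp), nt))
    truth_rows.append(("random_genes", "null"))
    profiles = pd.DataFrame(rows, columns=["species_id", "system_id", "total_nt"])
    truth = pd.DataFrame(truth_rows, columns=["system_id", "quadrant"])
    return profiles, truth


def fixture_ecologies() -> dict:
    """Named reference ecologies used throughout the test-bed.

    ``fig5`` is the fully parameterised reference habitat with its reported
    optimal strategy; ``fig5_reduced`` is the same habitat at a coarser
    intracellular resolution (Q=200) for routine runs.  ``virus_free`` has
    no influent virus; ``pcd_insensitive`` combines the directions that
    suppress PCD-sensitivity (low F, high G, low T, high E, high C);
    ``moi_*`` hold the extrinsic MOI C*psi0 at the four reference values.
    """
    fig5 = EcologyParams(A=28.0, B=0.05, C=1e-8, E=0.0125, F=4.0, G=1.0,
                         T=1.0, psi0=1e8, Q=1000)
    opt = StrategyParams(a=0.98716, r=0.00584)
    out = {
        "fig5": dict(eco=fig5, reference_optimum=opt),
        "fig5_reduced": dict(eco=fig5.replace(Q=200), reference_optimum=opt),
        "virus_free": dict(eco=fig5.replace(psi0=0.0, Q=200)),
        "pcd_insensitive": dict(eco=EcologyParams(
            A=28.0, B=0.05, C=1e-7, E=0.05, F=0.8, G=2.0, T=0.2,
            psi0=1e6, Q=60)),
        # high-skew burst regime: replication slow enough that a burst's
        # expected offspring stays below replacement, so the host persists
        # under influent pressure; most infected cells idle at low loads
        # while newborn-size cells that complete the cascade lyse at the
        # lethal concentration, giving the two-peaked burst distribution
        "burst_bimodal": dict(
            eco=EcologyParams(A=28.0, B=0.2, C=1e-7, E=0.0125, F=0.4,
                              G=1.0, T=1.0, psi0=1e6, Q=100),
            strategy=StrategyParams(a=0.0, r=0.0005)),
        # same habitat with the PCD threshold set just below the saturated
        # arrested cells' concentration: PCD fires at a substantial rate,
        # but only on division-arrested cells that could never be cured —
        # zero expected progeny, so PCD competency is selectively neutral
        "pcd_neutral": dict(
            eco=EcologyParams(A=28.0, B=0.2, C=1e-7, E=0.0125, F=0.4,
                              G=1.0, T=1.0, psi0=1e6, Q=100),
            strategy=StrategyParams(a=0.5, r=0.0005)),
    }
    for moi in (0.01, 0.1, 1.0, 100.0):
        out[f"moi_{moi:g}"] = dict(eco=fig5.replace(
            psi0=moi / fig5.C, Q=200))
    return out
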