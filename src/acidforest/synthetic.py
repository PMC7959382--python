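"""Clade-structured synthetic strain populations with planted causal loci.

The generator emulates the structure of a two-subspecies dairy *Lactococcus
lactis* collection: a shared core genome, clade-biased accessory gene
families, and a small number of *causal blocks* — operon-like groups of
co-occurring gene families whose presence speeds up milk acidification.
Each causal block can carry a *tag k-mer*, a 9-mer planted in the block's
gene sequences and scrubbed from every other sequence, giving the k-mer
representations an unambiguous handle on the planted signal.

Phenotypes follow an additive model on a positive internal "speed" scale:

    speed = b0 + Σ_blocks effect·presence + temperature shift (per clade)
            + yeast·yeast_effect + deepwell·volume_effect + ε_strain

clipped to the observed range of real acidification rates and emitted as
``V_max = −speed`` (negative, h⁻¹).  Kinetic pH curves are then synthesised
as logistic declines whose maximum sliding-window slope reproduces the
target V_max, optionally re-expressed as scanner hue through the inverse of
a calibration polynomial.

Every output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import reverse_complement
from .kinetics import (
    ALL_CONDITIONS,
    SAMPLE_STEP_H,
    CalibrationModel,
    Condition,
    PhCurve,
    PhenotypeTable,
    compute_vmax,
    fit_hue_calibration,
)

CLADES = ("A", "B")
#: subspecies label emitted for each clade
CLADE_SUBSPECIES = {"A": "lactis", "B": "cremoris"}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CausalBlock:
    """A group of co-occurring gene families with a phenotype effect.

    ``effect`` (h⁻¹) is added to the acidification speed of carrier strains;
    ``tag_kmer``, when set, is a 9-mer planted once in each of the block's
    gene sequences and guaranteed absent from all other genes.
    """

    name: str
    gene_ids: tuple[str, ...]
    carrier_prob: Mapping[str, float]
    effect: float
    tag_kmer: str | None = None

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("causal effect must be >= 0")
        for clade, p in self.carrier_prob.items():
            if clade not in CLADES or not 0 <= p <= 1:
                raise ValueError(f"bad carrier_prob for clade {clade!r}: {p}")
        if self.tag_kmer is not None:
            if len(self.tag_kmer) != 9 or not set(self.tag_kmer) <= set("ACGT"):
                raise ValueError("tag_kmer must be a 9-mer over ACGT")


@dataclass(frozen=True)
class ConditionEffects:
    """Condition-dependent shifts of the acidification speed (h⁻¹).

    Defaults make 30 °C optimal for both clades; at 40 °C only clade A
    (the *lactis*-like clade) recovers most of the deficit when yeast
    extract is present, via ``yeast_temp40_boost``.
    """

    temp_effect: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "A": {25: -0.10, 30: 0.0, 40: -0.06},
            "B": {25: -0.10, 30: 0.0, 40: -0.28},
        }
    )
    yeast_effect: float = 0.12
    volume_effect: float = 0.05  # deepwell minus lowwell
    yeast_temp40_boost: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.05, "B": 0.0}
    )

    def shift(self, clade: str, cond: Condition) -> float:
        s = self.temp_effect[clade][cond.temperature_C]
        if cond.yeast == "YE":
            s += self.yeast_effect
            if cond.temperature_C == 40:
                s += self.yeast_temp40_boost.get(clade, 0.0)
        if cond.volume == "DW":
            s += self.volume_effect
        return s


def null_config(seed: int = 1, n_strains: int = 100, **kwargs) -> "SimConfig":
    """A configuration with no genome–phenotype association at all.

    Causal effects are zeroed *and* the condition responses are made
    identical across clades — otherwise the clade-biased accessory genome
    would still predict the clade-specific temperature/yeast response, and a
    permutation null would rightly reject.  Used for null-calibration
    experiments.
    """
    symmetric = ConditionEffects(
        temp_effect={
            "A": {25: -0.10, 30: 0.0, 40: -0.17},
            "B": {25: -0.10, 30: 0.0, 40: -0.17},
        },
        yeast_effect=0.12,
        volume_effect=0.05,
        yeast_temp40_boost={"A": 0.0, "B": 0.0},
    )
    blocks = tuple(
        CausalBlock(
            name=b.name,
            gene_ids=b.gene_ids,
            carrier_prob=b.carrier_prob,
            effect=0.0,
            tag_kmer=b.tag_kmer,
        )
        for b in default_causal_blocks()
    )
    return SimConfig(
        n_strains=n_strains,
        causal_blocks=blocks,
        condition_effects=symmetric,
        seed=seed,
        **kwargs,
    )


def default_causal_blocks() -> tuple[CausalBlock, ...]:
    return (
        CausalBlock(
            name="cau1",
            gene_ids=("cau1_g1", "cau1_g2", "cau1_g3"),
            carrier_prob={"A": 0.70, "B": 0.35},
            effect=0.15,
            tag_kmer="ACGGTCACT",
        ),
        CausalBlock(
            name="cau2",
            gene_ids=("cau2_g1", "cau2_g2"),
            carrier_prob={"A": 0.40, "B": 0.60},
            effect=0.15,
            tag_kmer="GATTCACGG",
        ),
    )


@dataclass
class SimConfig:
    """Full specification of a synthetic population.

    The defaults are the package's reference study conditions: 200 strains in
    two clades (67% in clade A, mirroring the 230:112 subspecies ratio of the
    real collection), two causal blocks of effect 0.15 h⁻¹, strain-level
    noise of 0.03 h⁻¹, and V_max clipped to the observed real-data range
    [−0.96, −0.05] h⁻¹.
    """

    n_strains: int = 200
    clade_fraction: float = 0.67
    n_core_genes: int = 30
    n_accessory_genes: int = 100
    accessory_presence_prob: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.8, "B": 0.2}
    )
    causal_blocks: tuple[CausalBlock, ...] = field(default_factory=default_causal_blocks)
    condition_effects: ConditionEffects = field(default_factory=ConditionEffects)
    baseline_speed: float = 0.35  # b0, h⁻¹, at 30 °C / lowwell / no yeast
    clip_bounds: tuple[float, float] = (0.05, 0.96)  # on the positive speed scale
    noise_sd: float = 0.03
    missing_rate: float = 0.05
    gene_length_bp: tuple[int, int] = (300, 600)
    mutation_rate: float = 0.005  # per-base substitution per strain copy
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        for p in (self.clade_fraction, self.missing_rate, self.mutation_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for clade, p in self.accessory_presence_prob.items():
            if clade not in CLADES or not 0 <= p <= 1:
                raise ValueError(f"bad accessory_presence_prob for {clade!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.gene_length_bp
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_bp must be a positive (lo, hi) range")
        if self.clip_bounds[0] >= self.clip_bounds[1]:
            raise ValueError("clip bounds inverted")
        core = {f"core{i:04d}" for i in range(self.n_core_genes)}
        acc = {f"acc{i:04d}" for i in range(self.n_accessory_genes)}
        causal = [g for b in self.causal_blocks for g in b.gene_ids]
        if len(set(causal)) != len(causal):
            raise ValueError("causal gene ids repeated across blocks")
        if set(causal) & (core | acc):
            raise ValueError("causal gene id collides with core/accessory id")

    @property
    def core_gene_ids(self) -> list[str]:
        return [f"core{i:04d}" for i in range(self.n_core_genes)]

    @property
    def accessory_gene_ids(self) -> list[str]:
        return [f"acc{i:04d}" for i in range(self.n_accessory_genes)]

    @property
    def strain_ids(self) -> list[str]:
        return [f"strain{i:03d}" for i in range(1, self.n_strains + 1)]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated population, for recovery tests."""

    clade: pd.Series  # strain -> 'A' | 'B'
    presence: pd.DataFrame  # strains × all gene families (0/1)
    causal_effects: dict[str, float]  # block name -> effect
    causal_genes: dict[str, tuple[str, ...]]  # block name -> gene ids
    tag_kmers: dict[str, str]  # block name -> tag k-mer (if set)
    noise: pd.Series  # strain -> ε_strain
    gene_sequences: dict[str, dict[str, str]]  # gene -> strain -> sequence
    domain_assignment: dict[str, list[str]]  # gene -> Pfam-style accessions
    target_vmax: pd.DataFrame | None = None  # filled by generate_phenotypes

    @property
    def subspecies(self) -> dict[str, str]:
        return {s: CLADE_SUBSPECIES[c] for s, c in self.clade.items()}

    def block_presence(self, block: str) -> pd.Series:
        return self.presence[self.causal_genes[block][0]]


def _random_seq_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


_CODE_OF = {b: i for i, b in enumerate("ACGT")}


def _scrub_kmer(codes: np.ndarray, tags: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    """Mutate bases until none of ``tags`` (or their reverse complements) occur."""
    seq = _codes_to_str(codes)
    patterns = [t for t in tags] + [reverse_complement(t) for t in tags]
    changed = True
    while changed:
        changed = False
        for pat in patterns:
            pos = seq.find(pat)
            while pos >= 0:
                j = pos + len(pat) // 2
                codes[j] = (codes[j] + rng.integers(1, 4)) % 4
                seq = _codes_to_str(codes)
                pos = seq.find(pat)
                changed = True
    return codes


def generate_population(config: SimConfig) -> tuple[dict[str, list], SyntheticTruth]:
    """Draw a strain population: gene presence, sequences, clades.

    Returns ``(genomes, truth)`` where ``genomes`` maps each strain id to its
    FASTA records (one contig per present gene, Bio.SeqRecord with id
    ``strain|gene``).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(config.seed)
    strains = config.strain_ids
    n = config.n_strains
    n_a = int(round(config.clade_fraction * n))
    clade = pd.Series(["A"] * n_a + ["B"] * (n - n_a), index=strains, name="clade")

    families: list[str] = config.core_gene_ids + config.accessory_gene_ids
    causal_families = [g for b in config.causal_blocks for g in b.gene_ids]
    all_families = families + causal_families
    all_tags = [b.tag_kmer for b in config.causal_blocks if b.tag_kmer]

    # presence matrix
    presence = pd.DataFrame(0, index=strains, columns=all_families, dtype=np.int64)
    presence[config.core_gene_ids] = 1
    clade_arr = clade.to_numpy()
    for g in config.accessory_gene_ids:
        p = np.array([config.accessory_presence_prob[c] for c in clade_arr])
        presence[g] = (rng.random(n) < p).astype(np.int64)
    for block in config.causal_blocks:
        p = np.array([block.carrier_prob.get(c, 0.0) for c in clade_arr])
        carrier = (rng.random(n) < p).astype(np.int64)
        for g in block.gene_ids:
            presence[g] = carrier

    # base sequence per family; tags planted in causal genes, scrubbed elsewhere
    lo, hi = config.gene_length_bp
    tag_of_gene: dict[str, str] = {}
    tag_pos: dict[str, int] = {}
    for block in config.causal_blocks:
        if block.tag_kmer:
            for g in block.gene_ids:
                tag_of_gene[g] = block.tag_kmer
    base_codes: dict[str, np.ndarray] = {}
    for g in all_families:
        length = int(rng.integers(lo, hi + 1))
        codes = _random_seq_codes(rng, length)
        tag = tag_of_gene.get(g)
        if tag is not None:
            pos = int(rng.integers(0, length - len(tag) + 1))
            codes[pos : pos + len(tag)] = [_CODE_OF[b] for b in tag]
            tag_pos[g] = pos
            other = [t for t in all_tags if t != tag]
            if other:
                codes = _scrub_kmer(codes, other, rng)
                # scrubbing may not touch the planted tag region
                assert _codes_to_str(codes)[pos : pos + len(tag)] == tag
        else:
            codes = _scrub_kmer(codes, all_tags, rng)
        base_codes[g] = codes

    # per-strain copies: shared base with per-base substitutions; tag regions
    # kept mutation-free, and tags re-scrubbed from every non-tag copy
    gene_sequences: dict[str, dict[str, str]] = {}
    for g in all_families:
        base = base_codes[g]
        length = len(base)
        carriers = [s for s in strains if presence.at[s, g]]
        protect = np.zeros(length, dtype=bool)
        tag = tag_of_gene.get(g)
        if tag is not None:
            protect[tag_pos[g] : tag_pos[g] + len(tag)] = True
        copies: dict[str, str] = {}
        for s in carriers:
            mut = rng.random(length) < config.mutation_rate
            mut &= ~protect
            codes = base.copy()
            if mut.any():
                idx = np.nonzero(mut)[0]
                codes[idx] = (codes[idx] + rng.integers(1, 4, size=len(idx))) % 4
                scrub = all_tags if tag is None else [t for t in all_tags if t != tag]
                if scrub:
                    codes = _scrub_kmer(codes, scrub, rng)
            copies[s] = _codes_to_str(codes)
        gene_sequences[g] = copies

    # synthetic Pfam-domain assignment: causal families get a dedicated
    # accession (plus possibly shared ones); others draw 1-3 from a pool
    pool = [f"PF9{i:04d}.1" for i in range(max(10, len(all_families) // 3))]
    domain_assignment: dict[str, list[str]] = {}
    dedicated = 0
    for g in all_families:
        k = int(rng.integers(1, 4))
        accs = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        if g in causal_families:
            accs = [f"PF8{dedicated:04d}.1"] + accs[: k - 1]
            dedicated += 1
        domain_assignment[g] = accs

    genomes: dict[str, list] = {}
    for s in strains:
        recs = []
        for g in all_families:
            if presence.at[s, g]:
                recs.append(
                    SeqRecord(Seq(gene_sequences[g][s]), id=f"{s}|{g}", description="")
                )
        genomes[s] = recs

    noise = pd.Series(rng.normal(0.0, config.noise_sd, size=n), index=strains, name="noise")
    truth = SyntheticTruth(
        clade=clade,
        presence=presence,
        causal_effects={b.name: b.effect for b in config.causal_blocks},
        causal_genes={b.name: b.gene_ids for b in config.causal_blocks},
        tag_kmers={b.name: b.tag_kmer for b in config.causal_blocks if b.tag_kmer},
        noise=noise,
        gene_sequences=gene_sequences,
        domain_assignment=domain_assignment,
    )
    return genomes, truth


def generate_phenotypes(truth: SyntheticTruth, config: SimConfig) -> PhenotypeTable:
    """V_max per strain × condition under the additive speed model."""
    # derive the missingness stream from the config seed but offset, so the
    # phenotype draw does not perturb the population draw
    rng = np.random.default_rng(config.seed + 2**20)
    strains = list(truth.presence.index)
    lo, hi = config.clip_bounds
    table = pd.DataFrame(np.nan, index=strains, columns=[c.label for c in ALL_CONDITIONS])
    eff = config.condition_effects
    block_effect = {b.name: b.effect for b in config.causal_blocks}
    for s in strains:
        clade = truth.clade[s]
        genomic = sum(
            block_effect[name] * truth.presence.at[s, genes[0]]
            for name, genes in truth.causal_genes.items()
        )
        for cond in ALL_CONDITIONS:
            speed = (
                config.baseline_speed + genomic + eff.shift(clade, cond) + truth.noise[s]
            )
            table.at[s, cond.label] = -float(np.clip(speed, lo, hi))
    mask = rng.random(table.shape) < config.missing_rate
    table = table.mask(mask)
    table.index.name = "strain"
    truth.target_vmax = table.copy()
    return PhenotypeTable(table)


def synthetic_calibration_pairs(n: int = 25, seed: int = 0) -> list[tuple[float, float]]:
    """Hue↔pH calibration pairs from a smooth monotone dye response.

    Emulates measuring the indicator colour of milk buffered at known pH
    values between 4.0 and 6.5: hue rises monotonically (but not linearly)
    with pH over roughly 40–220 hue units.
    """
    rng = np.random.default_rng(seed)
    hue = np.linspace(40.0, 220.0, n)
    x = (hue - 40.0) / 180.0
    ph = 4.0 + 2.5 * x**1.3
    ph = ph + rng.normal(0, 0.005, size=n)
    return list(zip(hue.tolist(), ph.tolist()))


def default_calibration(seed: int = 0) -> CalibrationModel:
    return fit_hue_calibration(synthetic_calibration_pairs(seed=seed))


def _logistic_ph(times: np.ndarray, p0: float, p_end: float, r: float, t_mid: float) -> np.ndarray:
    z = np.clip(r * (times - t_mid), -700.0, 700.0)
    return p_end + (p0 - p_end) / (1.0 + np.exp(z))


def _window_vmax(values: np.ndarray, times: np.ndarray, w: int = 10) -> float:
    tw = np.lib.stride_tricks.sliding_window_view(times, w)
    yw = np.lib.stride_tricks.sliding_window_view(values, w)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
    return float(slopes.min())


def generate_ph_curves(
    phenotypes: PhenotypeTable,
    calib: CalibrationModel | None = None,
    duration_h: float = 12.0,
    p0: float = 6.5,
    p_end: float = 4.3,
) -> tuple[list[PhCurve], list[PhCurve]]:
    """Synthesize kinetic curves whose V_max reproduces the phenotype table.

    Each observed (strain, condition) gets a logistic pH decline whose
    steepness ``r`` is solved so that the maximum-negative 10-point window
    slope equals the target V_max; the hue variant re-expresses the same
    curve through the inverse of the calibration polynomial.

    Returns ``(ph_curves, hue_curves)``.
    """
    from scipy.optimize import brentq

    if calib is None:
        calib = default_calibration()
    times = np.round(np.arange(0.0, duration_h + SAMPLE_STEP_H / 2, SAMPLE_STEP_H), 10)
    t_mid = duration_h / 2.0
    amp = p0 - p_end
    if amp <= 0:
        raise ValueError("p0 must exceed p_end")

    r_lo, r_hi = 1e-3, 500.0
    vmax_hi = _window_vmax(_logistic_ph(times, p0, p_end, r_hi, t_mid), times)

    # inverse calibration by dense monotone interpolation
    hgrid = np.linspace(*calib.hue_range, 4096)
    pgrid = np.asarray(calib(hgrid), dtype=float)
    if pgrid[0] > pgrid[-1]:
        hgrid, pgrid = hgrid[::-1], pgrid[::-1]

    ph_curves: list[PhCurve] = []
    hue_curves: list[PhCurve] = []
    for strain in phenotypes.strain_ids:
        for cond in ALL_CONDITIONS:
            target = phenotypes.values.at[strain, cond.label]
            if np.isnan(target):
                continue
            if target > 0:
                raise ValueError("target V_max must be <= 0")
            if target == 0:
                values = np.full_like(times, p0)
            else:
                if target < vmax_hi:
                    raise ValueError(
                        f"target V_max {target} steeper than achievable "
                        f"({vmax_hi:.3f}) for pH drop {amp} over {duration_h} h"
                    )
                f = lambda r: _window_vmax(_logistic_ph(times, p0, p_end, r, t_mid), times) - target
                r = brentq(f, r_lo, r_hi, xtol=1e-10, rtol=1e-12)
                values = _logistic_ph(times, p0, p_end, r, t_mid)
            ph_curves.append(
                PhCurve(strain_id=strain, condition=cond, times=times.copy(), values=values, value_kind="pH")
            )
            hue_vals = np.interp(values, pgrid, hgrid)
            hue_curves.append(
                PhCurve(strain_id=strain, condition=cond, times=times.copy(), values=hue_vals, value_kind="hue")
            )
    return ph_curves, hue_curves


def emit_input_files(
    genomes: Mapping[str, list],
    truth: SyntheticTruth,
    phenotypes: PhenotypeTable,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the population in the formats the pipeline consumes.

    Emits per-strain FASTA, a Roary-style ``gene_presence_absence.csv``, a
    pfam_scan-style hit table, and the gene/phenotype matrices in the
    semicolon dialect.  Returns the paths keyed by artefact name.
    """
    from Bio import SeqIO

    from . import io as afio
    from .features import FeatureMatrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_dir = outdir / "genomes"
    genome_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    for s, recs in genomes.items():
        SeqIO.write(recs, genome_dir / f"{s}.fasta", "fasta")
    paths["genomes"] = genome_dir

    strains = list(truth.presence.index)
    genes = list(truth.presence.columns)
    cols: dict = {"Gene": genes, "Annotation": ["synthetic gene family"] * len(genes)}
    for s in strains:
        pres = truth.presence.loc[s]
        cols[s] = [f"{s}|{g}" if pres[g] else "" for g in genes]
    roary = pd.DataFrame(cols)
    paths["roary"] = outdir / "gene_presence_absence.csv"
    afio.write_roary(roary, paths["roary"])

    rows = []
    for g, accs in truth.domain_assignment.items():
        for s in strains:
            if not truth.presence.at[s, g]:
                continue
            for acc in accs:
                rows.append((f"{s}|{g}", acc, f"syn{acc.split('.')[0][2:]}"))
    pfam = pd.DataFrame(rows, columns=["seq_id", "hmm_acc", "hmm_name"])
    paths["pfam"] = outdir / "pfam_hits.txt"
    afio.write_pfamscan(pfam, paths["pfam"])

    gene_matrix = FeatureMatrix(
        representation="gene",
        values=truth.presence.copy(),
        subspecies=pd.Series(truth.subspecies, name="subspecies"),
    )
    paths["gene_matrix"] = outdir / "gene_matrix.txt"
    afio.write_matrix(gene_matrix, paths["gene_matrix"])

    paths["phenotypes"] = outdir / "phenotypes.txt"
    afio.write_phenotypes(phenotypes, paths["phenotypes"])
    return paths
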