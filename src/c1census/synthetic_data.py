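"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's real
inputs — strain proteomes plus a large decoy protein database, environmental
peptide fragments at known per-site gene dosages, radiotracer time courses
with an initial linear phase, and luminescence plates with a linear ATP
standard curve — without claiming sequence-level realism.

Sequence evolution is a point-substitution model at fixed per-site
probabilities.  What matters for testing best-hit assignment is only the
*ordering* of divergences:

    read-vs-source gene  <  paralog-vs-paralog  <  decoy-vs-focal

with enough margin that best hits are resolvable at the default fragment
length.  Parameter sets that break this ordering are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from c1census.atp import PlateSet
from c1census.kinetics import KILLED, LIVE, TimeCourse
from c1census.records import DECOY, FOCAL, PeptideRead, ProteinRecord

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

MARKER_GENE_ID = "recA"


# ---------------------------------------------------------------------------
# reference proteomes


@dataclass(frozen=True)
class ReferenceSet:
    """Focal-strain proteomes, decoy proteomes and paralog bookkeeping."""

    focal_proteomes: dict[str, list[ProteinRecord]]
    decoy_proteomes: dict[str, list[ProteinRecord]]
    paralog_groups: list[frozenset[str]]
    marker_gene_id: str = MARKER_GENE_ID

    def proteome(self, strain_id: str) -> list[ProteinRecord]:
        if strain_id in self.focal_proteomes:
            return self.focal_proteomes[strain_id]
        return self.decoy_proteomes[strain_id]

    def all_records(self) -> list[ProteinRecord]:
        out: list[ProteinRecord] = []
        for prot in self.focal_proteomes.values():
            out.extend(prot)
        for prot in self.decoy_proteomes.values():
            out.extend(prot)
        return out

    def gene(self, strain_id: str, gene_id: str) -> ProteinRecord:
        for rec in self.proteome(strain_id):
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(f"gene {gene_id!r} not found in strain {strain_id!r}")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point substitutions at per-site probability ``rate`` (new residue
    drawn uniformly from the 19 alternatives)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.nonzero(mask)[0]:
        choices = AA[AA != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def generate_reference_set(n_focal: int = 3, n_decoy: int = 5,
                           genes_per_proteome: int = 20, paralog_pairs: int = 2,
                           seed: int = 0, *,
                           gene_length_mean: int = 90, gene_length_jitter: int = 30,
                           ortholog_divergence: float = 0.05,
                           paralog_divergence: float = 0.35,
                           decoy_divergence: float = 0.60) -> ReferenceSet:
    """Build focal and decoy proteomes from shared ancestral gene families.

    Each gene family starts from one random ancestral protein; each focal
    strain carries a copy mutated at ``ortholog_divergence / 2`` (so focal
    copies sit about ``ortholog_divergence`` apart pairwise), each decoy
    strain a copy mutated at ``decoy_divergence``.  Paralog pairs add a
    second family member (suffix ``b``) mutated at ``paralog_divergence``
    from its partner, present in every focal strain.  The single-copy
    marker (recA role) is one ordinary family present in every strain.
    """
    if n_focal < 1 or n_decoy < 0 or genes_per_proteome < 1 or paralog_pairs < 0:
        raise ValueError("counts out of range")
    if paralog_pairs > genes_per_proteome - 1:
        raise ValueError("more paralog pairs than non-marker gene families")
    if not (0 <= ortholog_divergence < paralog_divergence < decoy_divergence <= 0.95):
        raise ValueError("divergence ordering read<paralog<decoy cannot hold "
                         "with these rates")
    if paralog_divergence - ortholog_divergence < 0.10 or \
            decoy_divergence - paralog_divergence < 0.10:
        raise ValueError("divergence levels too close for best-hit assignment "
                         "to be resolvable")
    rng = np.random.default_rng(seed)

    family_ids = [MARKER_GENE_ID] + [f"g{i:02d}" for i in range(1, genes_per_proteome)]
    lengths = {
        fam: int(rng.integers(gene_length_mean - gene_length_jitter,
                              gene_length_mean + gene_length_jitter + 1))
        if gene_length_jitter > 0 else gene_length_mean
        for fam in family_ids
    }
    ancestors = {fam: _random_protein(rng, lengths[fam]) for fam in family_ids}
    # paralog partners: one extra member per chosen family, diverged from the
    # family ancestor at paralog_divergence
    paralog_parents = family_ids[1:1 + paralog_pairs]
    paralog_ancestors = {
        f"{fam}b": _mutate(rng, ancestors[fam], paralog_divergence)
        for fam in paralog_parents
    }

    focal: dict[str, list[ProteinRecord]] = {}
    for i in range(n_focal):
        strain = f"FOC{i + 1:02d}"
        recs = [
            ProteinRecord(fam, strain, FOCAL,
                          _mutate(rng, ancestors[fam], ortholog_divergence / 2))
            for fam in family_ids
        ]
        recs += [
            ProteinRecord(pid, strain, FOCAL,
                          _mutate(rng, pseq, ortholog_divergence / 2))
            for pid, pseq in paralog_ancestors.items()
        ]
        focal[strain] = recs

    decoy: dict[str, list[ProteinRecord]] = {}
    for i in range(n_decoy):
        strain = f"DEC{i + 1:02d}"
        decoy[strain] = [
            ProteinRecord(fam, strain, DECOY,
                          _mutate(rng, ancestors[fam], decoy_divergence))
            for fam in family_ids
        ]

    groups = [frozenset({fam, f"{fam}b"}) for fam in paralog_parents]
    return ReferenceSet(focal, decoy, groups, MARKER_GENE_ID)


# ---------------------------------------------------------------------------
# metagenome reads


@dataclass(frozen=True)
class SiteSpec:
    """Sampling-site recipe: true per-site gene dosages and read budget."""

    site_id: str
    copy_number: dict[str, int]   # gene id -> per-genome dosage at this site
    decoy_fraction: float = 0.0
    fragment_length: int = 60     # residues per peptide read
    n_fragments: int = 1000
    seed: int = 0
    read_error: float = 0.05      # per-site substitution rate read-vs-gene

    def __post_init__(self):
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy_fraction must be in [0, 1)")
        if self.fragment_length < 10:
            raise ValueError("fragment_length must be >= 10")
        if any(c < 0 for c in self.copy_number.values()):
            raise ValueError("copy numbers must be non-negative")


def generate_metagenome(ref: ReferenceSet,
                        sites: list[SiteSpec]) -> tuple[list[PeptideRead], pd.DataFrame]:
    """Draw peptide fragments from the reference set at known dosages.

    Focal reads choose a source strain uniformly and a gene with probability
    proportional to ``copy_number * gene length`` (long genes shed more
    fragments per copy, which is exactly the bias recA normalisation divides
    back out).  Fragments start uniformly along the gene and are clamped to
    whole-gene reads when the gene is shorter than ``fragment_length``.
    Returns the reads plus their complete truth table.
    """
    focal_strains = sorted(ref.focal_proteomes)
    reads: list[PeptideRead] = []
    for site in sites:
        for gid in site.copy_number:
            ref.gene(focal_strains[0], gid)  # raises KeyError if absent
        rng = np.random.default_rng(site.seed)
        n_decoy_reads = int(round(site.decoy_fraction * site.n_fragments))
        n_focal_reads = site.n_fragments - n_decoy_reads
        genes = sorted(g for g, c in site.copy_number.items() if c > 0)
        if not genes and n_decoy_reads == 0:
            warnings.warn(f"site {site.site_id!r} is empty (no dosage, no decoys)",
                          stacklevel=2)
            continue
        weights = np.array([
            site.copy_number[g] * len(ref.gene(focal_strains[0], g)) for g in genes
        ], dtype=float)
        counter = 0
        if genes and n_focal_reads > 0:
            gene_idx = rng.choice(len(genes), size=n_focal_reads,
                                  p=weights / weights.sum())
            strain_idx = rng.integers(0, len(focal_strains), size=n_focal_reads)
            for gi, si in zip(gene_idx, strain_idx):
                strain = focal_strains[si]
                rec = ref.gene(strain, genes[gi])
                reads.append(_fragment(rng, rec, site, counter))
                counter += 1
        if n_decoy_reads > 0:
            if not ref.decoy_proteomes:
                raise ValueError("decoy_fraction > 0 but reference has no decoys")
            decoy_strains = sorted(ref.decoy_proteomes)
            all_decoy = [(s, r) for s in decoy_strains for r in ref.decoy_proteomes[s]]
            dweights = np.array([len(r) for _, r in all_decoy], dtype=float)
            picks = rng.choice(len(all_decoy), size=n_decoy_reads,
                               p=dweights / dweights.sum())
            for pi in picks:
                strain, rec = all_decoy[pi]
                reads.append(_fragment(rng, rec, site, counter))
                counter += 1
    truth = pd.DataFrame([
        {"read_id": r.read_id, "site_id": r.site_id,
         "source_gene": r.source_gene, "source_strain": r.source_strain}
        for r in reads
    ])
    return reads, truth


def _fragment(rng: np.random.Generator, rec: ProteinRecord, site: SiteSpec,
              index: int) -> PeptideRead:
    fl = min(site.fragment_length, len(rec))
    start = int(rng.integers(0, len(rec) - fl + 1))
    seq = _mutate(rng, rec.seq[start:start + fl], site.read_error)
    return PeptideRead(read_id=f"{site.site_id}_r{index:06d}", site_id=site.site_id,
                       seq=seq, source_gene=rec.gene_id, source_strain=rec.strain_id)


def reads_by_site(reads: list[PeptideRead]) -> dict[str, list[PeptideRead]]:
    out: dict[str, list[PeptideRead]] = {}
    for r in reads:
        out.setdefault(r.site_id, []).append(r)
    return out


# ---------------------------------------------------------------------------
# tracer time courses


@dataclass(frozen=True)
class TracerParams:
    """True rates and sampling design for one live/killed vial pair.

    Rates are in nmol per 10^10 cells per hour.  The cumulative curve is
    linear up to ``saturation_time`` and then approaches its plateau
    exponentially with scale ``saturation_sharpness`` (hours); the default
    sharpness gives an abrupt, near-plateau transition like an exhausted
    substrate pool.  The default noise keeps error bars smaller than plot
    symbols, matching well-replicated scintillation counts.
    """

    v_ox: float = 1.4
    v_inc: float = 0.6
    saturation_time: float = 3.0      # hours of linear accumulation
    cell_density: float = 4e7         # cells per mL
    volume: float = 4.0               # mL per vial
    noise_sd: float = 0.0005          # nmol, additive on each measurement
    n_timepoints: int = 8
    seed: int = 0
    dt: float = 1.0                   # hours between samples
    saturation_sharpness: float = 0.01  # hours; exponential approach scale

    def __post_init__(self):
        if self.v_ox < 0 or self.v_inc < 0:
            raise ValueError("rates must be non-negative")
        if self.saturation_time <= 0:
            raise ValueError("saturation_time must be positive")
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 timepoints")

    @property
    def cells_total(self) -> float:
        return self.cell_density * self.volume


def _effective_time(t: np.ndarray, t_sat: float, s: float) -> np.ndarray:
    """Linear time up to t_sat, then exponential approach to the plateau
    (continuous value and first derivative at t_sat)."""
    tau = np.where(t <= t_sat, t, t_sat + s * (1.0 - np.exp(-(np.maximum(t, t_sat) - t_sat) / s)))
    return tau


def generate_tracer_timecourse(p: TracerParams) -> tuple[TimeCourse, TimeCourse]:
    """One live and one formalin-killed time course with shared design."""
    rng = np.random.default_rng(p.seed)
    t = np.arange(p.n_timepoints, dtype=float) * p.dt
    tau = _effective_time(t, p.saturation_time, p.saturation_sharpness)
    scale = p.cells_total / 1e10
    curves = {}
    for treatment, (vo, vi) in ((LIVE, (p.v_ox, p.v_inc)), (KILLED, (0.0, 0.0))):
        ox = vo * scale * tau + (rng.normal(0, p.noise_sd, len(t)) if p.noise_sd > 0 else 0.0)
        inc = vi * scale * tau + (rng.normal(0, p.noise_sd, len(t)) if p.noise_sd > 0 else 0.0)
        curves[treatment] = TimeCourse(times=t, oxidized=np.asarray(ox, dtype=float),
                                       incorporated=np.asarray(inc, dtype=float),
                                       treatment=treatment, cells_total=p.cells_total)
    return curves[LIVE], curves[KILLED]


def timecourse_frame(live: TimeCourse, killed: TimeCourse) -> pd.DataFrame:
    rows = []
    for tc in (live, killed):
        for i in range(len(tc.times)):
            rows.append({"time_h": tc.times[i], "oxidized_nmol": tc.oxidized[i],
                         "incorporated_nmol": tc.incorporated[i],
                         "treatment": tc.treatment, "cells_total": tc.cells_total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ATP plates


@dataclass(frozen=True)
class PlateParams:
    """True standard curve and per-treatment ATP contents for one plate."""

    standard_concs: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0)  # nM ATP
    curve_slope: float = 1000.0       # luminescence units per nM
    curve_intercept: float = 50.0     # luminescence units (reagent background)
    treatment_means: dict[str, float] = field(
        default_factory=lambda: {"T": 48.0, "N": 16.0, "P": 160.0})  # zg/cell
    replicate_sd: float = 2.0         # zg/cell between replicate wells
    n_replicates: int = 3
    cell_count: float = 6e6           # cells per sample well
    seed: int = 0
    well_volume_l: float = 2e-5       # 20 uL sample per well
    lum_noise_sd: float = 0.0         # luminescence noise on standard wells

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        concs = np.asarray(self.standard_concs, dtype=float)
        if len(concs) < 3 or np.any(np.diff(concs) <= 0):
            raise ValueError("standard_concs must be >= 3 strictly increasing values")


def _zg_to_lum(zg_per_cell: float, p: PlateParams) -> float:
    grams = zg_per_cell * 1e-21 * p.cell_count
    moles = grams / 507.18
    conc_nm = moles / p.well_volume_l * 1e9
    return p.curve_slope * conc_nm + p.curve_intercept


def generate_atp_plate(p: PlateParams) -> PlateSet:
    """Standard wells on the true line plus replicate T/N/P sample wells."""
    rng = np.random.default_rng(p.seed)
    rows = []
    for i, conc in enumerate(p.standard_concs):
        lum = p.curve_slope * conc + p.curve_intercept
        if p.lum_noise_sd > 0:
            lum += rng.normal(0, p.lum_noise_sd)
        rows.append({"well": f"S{i + 1:02d}", "kind": "standard", "label": "",
                     "conc": conc, "luminescence": lum})
    for label in sorted(p.treatment_means):
        mean = p.treatment_means[label]
        for j in range(p.n_replicates):
            zg = mean + (rng.normal(0, p.replicate_sd) if p.replicate_sd > 0 else 0.0)
            zg = max(zg, 0.0)
            rows.append({"well": f"{label}{j + 1:02d}", "kind": "sample",
                         "label": label, "conc": float("nan"),
                         "luminescence": _zg_to_lum(zg, p)})
    return PlateSet(data=pd.DataFrame(rows), cells_in_well=p.cell_count,
                    well_volume_l=p.well_volume_l)
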