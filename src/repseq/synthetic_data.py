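"""Synthetic cohorts, repertoires, UMI-tagged reads and paired fixtures.

Everything downstream of the sequencer is testable against this
generator because it carries its own ground truth: per-donor richness
trajectories with a known generative %/year slope, clone registries with
known frequencies, retention between visits, read-level UMI→clonotype
sidecars, and dual-TCRα rates for the single-cell fixtures.

The emulated study design: a 30-donor longitudinal cohort (15 male,
15 female; first-visit ages spanning the late 20s to mid 70s; two visits
roughly 9 years apart), four sorted subsets (CD4/CD8 × naive/memory) per
visit, both TCR chains sequenced with 12-bp UMIs at ~30 reads per UMI.
Clone sizes are log-normal on frequencies by default (heavy upper tail
emulating clonal expansion); power-law and uniform laws are selectable.
Scale (per-subset richness in the low thousands) is reduced relative to
real repertoires (1e4–1e6) to keep simulation desk-sized; the structure,
not the magnitude, is what downstream code consumes.

Determinism: all randomness derives from ``GenerativeConfig.seed`` (and
per-call seeds); a fixed seed reproduces tables bitwise and FASTQ
bytewise. Clone registries are derived lazily from per-(donor, visit,
subset, chain) seeds so cohort-level analyses that never touch clones
(e.g. slope inference) stay cheap.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import pairing
from .cell_accounting import SUBSETS, DonorProfile
from .reference import MiniReference, default_reference
from .umi_pipeline import CHAINS, UMI_LENGTH, ClonotypeTable, SampleId, \
    TABLE_COLUMNS

NUCLEOTIDES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = np.array(sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
    - STOP_CODONS))

CLONE_SIZE_LAWS = ("lognormal", "powerlaw", "uniform")

_REFERENCE: Optional[MiniReference] = None


def get_reference() -> MiniReference:
    """The bundled mini V/J reference (shared generator/annotation)."""
    global _REFERENCE
    if _REFERENCE is None:
        _REFERENCE = default_reference()
    return _REFERENCE


class ConfigurationError(ValueError):
    pass


class SimulationError(ValueError):
    pass


def _default_richness() -> dict:
    return {"CD4_naive": 4000, "CD4_memory": 1500,
            "CD8_naive": 3000, "CD8_memory": 1000}


def _default_slopes() -> dict:
    # naive-subset %/year declines set to the published longitudinal
    # estimates; memory subsets showed no significant richness change
    return {("CD4_naive", "alpha"): -0.66, ("CD4_naive", "beta"): -2.27,
            ("CD8_naive", "alpha"): -2.19, ("CD8_naive", "beta"): -3.48,
            ("CD4_memory", "alpha"): 0.0, ("CD4_memory", "beta"): 0.0,
            ("CD8_memory", "alpha"): 0.0, ("CD8_memory", "beta"): 0.0}


@dataclass
class GenerativeConfig:
    """All knobs of the synthetic study, with the emulated-study defaults."""

    n_donors: int = 30
    visit_gap_years: tuple[float, float] = (7.0, 11.0)  # uniform; mean 9 y
    age_range: tuple[float, float] = (28.0, 76.0)  # first-visit ages
    clone_size_distribution: str = "lognormal"
    clone_size_params: dict = field(
        default_factory=lambda: {"sigma": 1.5})
    true_richness_by_subset: dict = field(default_factory=_default_richness)
    annual_pct_change: dict = field(default_factory=_default_slopes)
    retention_fraction: float = 0.10
    reads_per_umi: int = 30
    error_rate: float = 0.001
    dual_alpha_fraction: float = 0.13
    stop_codon_fraction: float = 0.0
    cells_per_clone_mean: int = 10
    donor_intercept_sd: float = 0.3  # log10 units
    residual_sd: float = 0.1  # log10 units
    cdr3_codons: tuple[int, int] = (4, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_size_distribution not in CLONE_SIZE_LAWS:
            raise ConfigurationError(
                f"unknown clone-size distribution "
                f"{self.clone_size_distribution!r}; "
                f"choose from {CLONE_SIZE_LAWS}")
        for name in ("retention_fraction", "error_rate",
                     "dual_alpha_fraction", "stop_codon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_donors < 1:
            raise ConfigurationError("n_donors must be >= 1")
        if any(r < 1 for r in self.true_richness_by_subset.values()):
            raise ConfigurationError("richness must be >= 1")
        if self.reads_per_umi < 1:
            raise ConfigurationError("reads_per_umi must be >= 1")

    def pct_change(self, subset: str, chain: str) -> float:
        return self.annual_pct_change.get((subset, chain), 0.0)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "annual_pct_change" in raw:
            raw["annual_pct_change"] = {
                tuple(k.split("/")): v
                for k, v in raw["annual_pct_change"].items()}
        for name in ("visit_gap_years", "age_range", "cdr3_codons"):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["annual_pct_change"] = {"/".join(k): v
                                    for k, v in self.annual_pct_change.items()}
        for name in ("visit_gap_years", "age_range", "cdr3_codons"):
            raw[name] = list(raw[name])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# clone registries
# ---------------------------------------------------------------------------

def _make_cdr3s(rng: np.random.Generator, n: int, codon_range: tuple,
                stop_fraction: float, used_aa: set) -> list[tuple[str, str]]:
    """Generate ``n`` in-frame CDR3s with unique amino-acid sequences."""
    out: list[tuple[str, str]] = []
    lo, hi = codon_range
    while len(out) < n:
        n_codons = int(rng.integers(lo, hi + 1))
        codons = list(rng.choice(SENSE_CODONS, size=n_codons))
        if stop_fraction and rng.random() < stop_fraction:
            pos = int(rng.integers(0, n_codons))
            codons[pos] = str(rng.choice(sorted(STOP_CODONS)))
        nt = "".join(codons)
        aa = str(Seq(nt).translate())
        if aa in used_aa:
            continue
        used_aa.add(aa)
        out.append((nt, aa))
    return out


def _make_clones(rng: np.random.Generator, n: int, chain: str,
                 reference: MiniReference, codon_range: tuple,
                 stop_fraction: float, used_aa: set) -> list[tuple]:
    """Clone keys (v_gene, j_gene, cdr3_nt, cdr3_aa) for one repertoire."""
    v_names = reference.v_names(chain)
    j_names = reference.j_names(chain)
    vs = rng.choice(v_names, size=n)
    js = rng.choice(j_names, size=n)
    cdr3s = _make_cdr3s(rng, n, codon_range, stop_fraction, used_aa)
    return [(str(v), str(j), nt, aa)
            for v, j, (nt, aa) in zip(vs, js, cdr3s)]


def _clone_weights(rng: np.random.Generator, n: int, law: str,
                   params: dict) -> np.ndarray:
    if law == "lognormal":
        return rng.lognormal(mean=0.0, sigma=params.get("sigma", 1.5),
                             size=n)
    if law == "powerlaw":
        return 1.0 + rng.pareto(params.get("exponent", 2.0), size=n)
    if law == "uniform":
        return np.ones(n)
    raise ConfigurationError(f"unknown clone-size distribution {law!r}")


@dataclass
class TruthRecord:
    """Ground truth for one donor: trajectories, clones, retention.

    Clone registries, frequency vectors and retained-key lists are
    derived deterministically from per-combination seeds on first access
    and cached, so cohort-level analyses that never touch clones stay
    cheap.
    """

    donor: str
    donor_index: int
    ages: tuple[float, float]
    richness: dict  # (visit, subset, chain) -> int
    paired_richness: dict  # (visit, lineage) -> float
    config: GenerativeConfig
    _cache: dict = field(default_factory=dict, repr=False)

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.config.seed, self.donor_index, *key])

    def _registry(self, subset: str, chain: str) -> dict:
        """Visit-1/visit-2 clone lists plus retained keys."""
        cache_key = ("registry", subset, chain)
        if cache_key in self._cache:
            return self._cache[cache_key]
        cfg = self.config
        si = SUBSETS.index(subset)
        ci = CHAINS.index(chain)
        reference = get_reference()
        used_aa: set = set()
        r1 = self.richness[(1, subset, chain)]
        r2 = self.richness[(2, subset, chain)]
        v1 = _make_clones(self._rng(si, ci, 1), r1, chain, reference,
                          cfg.cdr3_codons, cfg.stop_codon_fraction, used_aa)
        keep = self._rng(si, ci, 2).random(r1) < cfg.retention_fraction
        retained = [c for c, k in zip(v1, keep) if k][:r2]
        n_new = r2 - len(retained)
        new = _make_clones(self._rng(si, ci, 3), n_new, chain, reference,
                           cfg.cdr3_codons, cfg.stop_codon_fraction,
                           used_aa)
        v2 = retained + new
        reg = {"visit1": v1, "visit2": v2, "retained": retained}
        self._cache[cache_key] = reg
        return reg

    def clones(self, visit: int, subset: str, chain: str) -> list[tuple]:
        return self._registry(subset, chain)[f"visit{visit}"]

    def retained_clones(self, subset: str, chain: str) -> list[tuple]:
        """Clones persisting from visit 1 to visit 2."""
        return self._registry(subset, chain)["retained"]

    def cell_counts(self, visit: int, subset: str,
                    chain: str) -> np.ndarray:
        """Integer cells per clone in the donor's (synthetic) population.

        Every clone carries at least one cell; the remaining population
        mass is multinomial on the configured clone-size weights.
        """
        cache_key = ("counts", visit, subset, chain)
        if cache_key in self._cache:
            return self._cache[cache_key]
        cfg = self.config
        si = SUBSETS.index(subset)
        ci = CHAINS.index(chain)
        n = self.richness[(visit, subset, chain)]
        rng = self._rng(si, ci, 4 + visit)
        if cfg.clone_size_distribution == "uniform":
            counts = np.full(n, cfg.cells_per_clone_mean, dtype=np.int64)
        else:
            w = _clone_weights(rng, n, cfg.clone_size_distribution,
                               cfg.clone_size_params)
            extra = n * (cfg.cells_per_clone_mean - 1)
            counts = np.ones(n, dtype=np.int64)
            if extra > 0:
                counts += rng.multinomial(extra, w / w.sum())
        self._cache[cache_key] = counts
        return counts

    def frequencies(self, visit: int, subset: str,
                    chain: str) -> np.ndarray:
        """True clone frequency vector (sums to 1)."""
        counts = self.cell_counts(visit, subset, chain)
        return counts / counts.sum()

    def to_json(self, path) -> None:
        payload = {"donor": self.donor, "donor_index": self.donor_index,
                   "ages": list(self.ages),
                   "richness": {"|".join(map(str, k)): v
                                for k, v in self.richness.items()},
                   "paired_richness": {"|".join(map(str, k)): v
                                       for k, v in
                                       self.paired_richness.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_BASE_FRACTIONS = {"CD4_naive": 0.15, "CD4_memory": 0.20,
                   "CD8_naive": 0.07, "CD8_memory": 0.11}


def _profile(rng: np.random.Generator, donor: str, visit: int, age: float,
             sex: str) -> DonorProfile:
    if sex == "male":
        height = float(np.clip(rng.normal(1.76, 0.07), 1.55, 2.00))
        weight = float(np.clip(rng.normal(82, 11), 55, 130))
    else:
        height = float(np.clip(rng.normal(1.62, 0.06), 1.45, 1.85))
        weight = float(np.clip(rng.normal(68, 10), 45, 110))
    # mild age-related lymphopenia, as seen in the emulated cohort
    lymph = float(np.clip(rng.normal(2400 - 8.0 * (age - 30), 350),
                          800, 4500))
    fractions = {}
    for subset, base in _BASE_FRACTIONS.items():
        jitter = float(rng.lognormal(0.0, 0.15))
        drift = 1.0 - 0.004 * (age - 30) if subset.endswith("naive") else 1.0
        fractions[subset] = float(np.clip(base * jitter * max(drift, 0.2),
                                          0.005, 0.5))
    return DonorProfile(donor=donor, visit=visit, age=age, sex=sex,
                        height_m=height, weight_kg=weight,
                        lymphocytes_per_ul=lymph,
                        subset_fractions=fractions)


def simulate_cohort(config: GenerativeConfig
                    ) -> tuple[list[DonorProfile], list[TruthRecord]]:
    """Generate donor profiles (two visits each) and truth records.

    log10 richness at visit 1 is the subset baseline plus an age trend at
    the configured %/year slope, a donor random intercept and residual
    noise; visit 2 compounds the visit-1 value by (1 + pct/100)^gap with
    fresh residual noise. Zero slope and zero noise therefore reproduce
    visit 1 exactly at visit 2.
    """
    rng = np.random.default_rng([config.seed, 987])
    profiles: list[DonorProfile] = []
    truths: list[TruthRecord] = []
    age_ref = float(np.mean(config.age_range))
    for d in range(config.n_donors):
        donor = f"D{d + 1:02d}"
        sex = "male" if d % 2 == 0 else "female"
        age1 = float(rng.uniform(*config.age_range))
        gap = float(rng.uniform(*config.visit_gap_years))
        age2 = age1 + gap
        profiles.append(_profile(rng, donor, 1, age1, sex))
        profiles.append(_profile(rng, donor, 2, age2, sex))
        richness: dict = {}
        for subset in SUBSETS:
            base = config.true_richness_by_subset.get(subset)
            if base is None:
                continue
            for chain in CHAINS:
                pct = config.pct_change(subset, chain)
                slope_log10 = np.log10(1.0 + pct / 100.0)
                intercept = rng.normal(0.0, config.donor_intercept_sd)
                eps1 = rng.normal(0.0, config.residual_sd)
                eps2 = rng.normal(0.0, config.residual_sd)
                log_r1 = (np.log10(base) + slope_log10 * (age1 - age_ref)
                          + intercept + eps1)
                r1 = max(1, round(10.0 ** log_r1))
                r2 = max(1, round(r1 * (1.0 + pct / 100.0) ** gap
                                  * 10.0 ** eps2))
                richness[(1, subset, chain)] = r1
                richness[(2, subset, chain)] = r2
        paired: dict = {}
        for visit in (1, 2):
            for lineage in ("CD4", "CD8"):
                subsets = [s for s in SUBSETS if s.startswith(lineage)
                           and (visit, s, "alpha") in richness]
                if not subsets:
                    continue
                a = sum(richness[(visit, s, "alpha")] for s in subsets)
                b = sum(richness[(visit, s, "beta")] for s in subsets)
                paired[(visit, lineage)] = pairing.apply_pairing_equation(
                    pairing.DEFAULT_MODELS[lineage], a, b)
        truths.append(TruthRecord(donor=donor, donor_index=d,
                                  ages=(age1, age2), richness=richness,
                                  paired_richness=paired, config=config))
    return profiles, truths


# ---------------------------------------------------------------------------
# repertoire sampling
# ---------------------------------------------------------------------------

def simulate_repertoire(truth: TruthRecord, subset: str, chain: str,
                        n_cells: int, seed: int,
                        visit: int = 1) -> ClonotypeTable:
    """Sample ``n_cells`` cells without replacement from the donor's
    population and return the observed clonotype table (one UMI-tagged
    molecule per sampled cell)."""
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    counts = truth.cell_counts(visit, subset, chain)
    population = int(counts.sum())
    if n_cells > population:
        raise SimulationError(
            f"n_cells={n_cells} exceeds population size {population}")
    rng = np.random.default_rng(seed)
    sampled = rng.multivariate_hypergeometric(counts, n_cells)
    clones = truth.clones(visit, subset, chain)
    rows = [(chain, v, j, nt, aa, int(c))
            for (v, j, nt, aa), c in zip(clones, sampled) if c > 0]
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    sample = SampleId(truth.donor, visit, subset, chain)
    return ClonotypeTable(sample, df)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _draw_umis(rng: np.random.Generator, n: int, used: set) -> list[str]:
    out = []
    while len(out) < n:
        umi = "".join(rng.choice(NUCLEOTIDES, size=UMI_LENGTH))
        if umi not in used:
            used.add(umi)
            out.append(umi)
    return out


def simulate_reads(table: ClonotypeTable, reads_per_umi: int,
                   error_rate: float, barcode: str, seed: int,
                   reference: Optional[MiniReference] = None,
                   quality: int = 35
                   ) -> tuple[list[SeqRecord], dict]:
    """Emit UMI-tagged reads for a clonotype table.

    Each UMI of each clonotype yields exactly ``reads_per_umi`` reads of
    layout barcode + 12-bp UMI + V-tag + CDR3nt + J-tag, with per-base
    substitution errors applied to the TCR region only. Returns the reads
    and a truth sidecar mapping UMI → clonotype key.
    """
    if reads_per_umi < 1:
        raise SimulationError("reads_per_umi must be >= 1")
    reference = reference or get_reference()
    rng = np.random.default_rng(seed)
    used_umis: set = set()
    reads: list[SeqRecord] = []
    sidecar: dict[str, tuple] = {}
    idx = 0
    for row in table.df.itertuples(index=False):
        tcr_nt = (reference.v(row.v_call).tag + row.junction
                  + reference.j(row.j_call).tag)
        key = (row.chain, row.v_call, row.j_call, row.junction_aa,
               row.junction)
        for umi in _draw_umis(rng, int(row.duplicate_count), used_umis):
            sidecar[umi] = key
            for _ in range(reads_per_umi):
                seq = barcode + umi + _mutate(rng, tcr_nt, error_rate)
                rec = SeqRecord(Seq(seq), id=f"read_{idx:07d}",
                                description="")
                rec.letter_annotations["phred_quality"] = \
                    [quality] * len(seq)
                reads.append(rec)
                idx += 1
    return reads, sidecar


def write_fastq(reads: Sequence[SeqRecord], path) -> None:
    from Bio import SeqIO
    with open(path, "w") as fh:
        SeqIO.write(reads, fh, "fastq")


# ---------------------------------------------------------------------------
# single-cell paired fixtures
# ---------------------------------------------------------------------------

def simulate_paired_sc(n_cells: int, dual_alpha_fraction: float, seed: int,
                       lineage: str = "CD4",
                       n_clones: Optional[int] = None) -> pd.DataFrame:
    """Single-cell paired αβ table: 1 TCRβ and 1 or 2 TCRα per cell.

    Chains are drawn from log-normal-weighted clone pools; a cell is
    dual-α with probability ``dual_alpha_fraction`` (its second α is a
    distinct clone). Long format: cell_id, chain, v_gene, j_gene,
    cdr3_nt, cdr3_aa.
    """
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    if not 0.0 <= dual_alpha_fraction <= 1.0:
        raise SimulationError("dual_alpha_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    reference = get_reference()
    n_clones = n_clones or max(50, n_cells // 5)
    pools = {}
    for chain in CHAINS:
        clones = _make_clones(rng, n_clones, chain, reference, (4, 12),
                              0.0, set())
        w = rng.lognormal(0.0, 1.0, size=n_clones)
        pools[chain] = (clones, w / w.sum())
    rows = []
    beta_clones, beta_p = pools["beta"]
    alpha_clones, alpha_p = pools["alpha"]
    beta_idx = rng.choice(n_clones, size=n_cells, p=beta_p)
    alpha_idx = rng.choice(n_clones, size=n_cells, p=alpha_p)
    dual = rng.random(n_cells) < dual_alpha_fraction
    # second α of dual cells must be a distinct clone: redraw collisions
    second_idx = rng.choice(n_clones, size=n_cells, p=alpha_p)
    clash = dual & (second_idx == alpha_idx)
    while clash.any():
        second_idx[clash] = rng.choice(n_clones, size=int(clash.sum()),
                                       p=alpha_p)
        clash = dual & (second_idx == alpha_idx)
    for i in range(n_cells):
        cell = f"cell_{i:06d}"
        rows.append((cell, "beta", *beta_clones[beta_idx[i]]))
        rows.append((cell, "alpha", *alpha_clones[alpha_idx[i]]))
        if dual[i]:
            rows.append((cell, "alpha", *alpha_clones[second_idx[i]]))
    return pd.DataFrame(rows, columns=["cell_id", "chain", "v_gene",
                                       "j_gene", "cdr3_nt", "cdr3_aa"])
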