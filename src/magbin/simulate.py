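"""Ground-truthed synthetic metagenome communities.

Emulates the inputs the binning pipeline sees in a real cohort study:
reference genomes with controlled GC content, strain variants at a nominal
per-base substitution rate, fragmentation into scaftigs, log-normal genome
abundances across samples, and noisy per-scaftig depths proportional to
genome abundance.  No read-level simulation: depths are real-valued because
everything downstream consumes correlations, not read counts.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed reproduces identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._sequtils import gc_content

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    """Specification of one genome (or strain variant) to simulate.

    Parameters
    ----------
    id : str
        Unique genome identifier.
    length : int
        Genome length in bases (ignored for strain variants, which inherit
        the parent's length).
    gc_target : float
        Target GC fraction in [0, 1].
    copy_of : str, optional
        Parent genome id; when set the genome is a strain variant of the
        parent, derived by substitutions only.
    divergence : float
        Per-base substitution probability for strain variants.
    """

    id: str
    length: int = 0
    gc_target: float = 0.5
    copy_of: str | None = None
    divergence: float = 0.0

    def __post_init__(self):
        if self.copy_of is None and self.length <= 0:
            raise ValueError(f"GenomeSpec {self.id}: length must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError(f"GenomeSpec {self.id}: gc_target outside [0, 1]")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"GenomeSpec {self.id}: divergence outside [0, 1]")
        if self.divergence > 0 and self.copy_of is None:
            raise ValueError(f"GenomeSpec {self.id}: divergence requires copy_of")


@dataclass
class Scaftig:
    """A contiguous gap-free sequence with its (synthetic) provenance."""

    id: str
    sequence: str
    genome_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass
class CommunityTruth:
    """Everything needed to score a binning result against ground truth."""

    genomes: dict[str, str]                 # id -> sequence
    scaftigs: list[Scaftig] = field(default_factory=list)
    abundance: pd.DataFrame | None = None   # genomes x samples
    seed: int = 0

    @property
    def scaftig_origin(self) -> dict[str, str]:
        return {s.id: s.genome_id for s in self.scaftigs}


def simulate_genomes(specs: list[GenomeSpec], seed: int) -> list[tuple[str, str]]:
    """Simulate genome sequences from specs.

    GC is controlled by per-base biased sampling: P(G or C) = gc_target.
    Strain variants (``copy_of`` set) copy the parent and substitute each
    base independently with probability ``divergence``; a substitution
    always changes the base (uniform over the other three).
    """
    if not specs:
        raise ValueError("simulate_genomes: empty spec list")
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("simulate_genomes: duplicate genome ids")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for spec in specs:
        if spec.copy_of is None:
            is_gc = rng.random(spec.length) < spec.gc_target
            half = rng.integers(0, 2, spec.length)
            codes = np.where(is_gc, np.where(half == 0, 2, 1), np.where(half == 0, 0, 3))
            out[spec.id] = "".join(_BASES[codes])
        else:
            if spec.copy_of not in out:
                raise ValueError(
                    f"simulate_genomes: {spec.id} copies unknown genome {spec.copy_of!r}"
                )
            parent = np.frombuffer(out[spec.copy_of].encode("ascii"), dtype=np.uint8)
            codes = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), parent)
            hit = rng.random(len(codes)) < spec.divergence
            # shift by 1..3 mod 4: substitution never returns the same base
            shift = rng.integers(1, 4, hit.sum())
            codes = codes.copy()
            codes[hit] = (codes[hit] + shift) % 4
            out[spec.id] = "".join(_BASES[codes])
    return [(i, out[i]) for i in ids]


def fragment_genome(
    genome: str,
    min_len: int,
    max_len: int,
    seed: int,
    genome_id: str = "g",
) -> list[Scaftig]:
    """Tile a genome into non-overlapping scaftigs.

    Scaftig lengths are drawn uniformly from [min_len, max_len]; a terminal
    remainder shorter than min_len is dropped.  Ids follow
    ``genomeID|index|start-end`` with 0-based half-open coordinates.
    """
    if min_len < 1:
        raise ValueError("fragment_genome: min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("fragment_genome: max_len < min_len")
    if len(genome) < min_len:
        warnings.warn(
            f"fragment_genome: genome of {len(genome)} bp shorter than min_len "
            f"{min_len}; no scaftigs emitted",
            stacklevel=2,
        )
        return []
    rng = np.random.default_rng(seed)
    scaftigs = []
    pos = 0
    idx = 0
    n = len(genome)
    while n - pos >= min_len:
        length = min(int(rng.integers(min_len, max_len + 1)), n - pos)
        end = pos + length
        scaftigs.append(
            Scaftig(
                id=f"{genome_id}|{idx}|{pos}-{end}",
                sequence=genome[pos:end],
                genome_id=genome_id,
                start=pos,
                end=end,
            )
        )
        pos = end
        idx += 1
    return scaftigs


def simulate_abundance(
    genome_ids: list[str],
    n_samples: int,
    seed: int,
    mean_sigma: float = 1.0,
    sample_sigma: float = 1.0,
) -> pd.DataFrame:
    """Log-normal genome abundances with per-genome mean profiles.

    Each genome gets a log-mean drawn once (spread ``mean_sigma``); each
    sample then draws around that mean (spread ``sample_sigma``).  The
    shared per-genome mean guarantees co-abundance structure: scaftigs of
    one genome track each other across samples.
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, mean_sigma, size=len(genome_ids))
    vals = np.exp(mu[:, None] + rng.normal(0.0, sample_sigma, size=(len(genome_ids), n_samples)))
    samples = [f"sample_{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(vals, index=genome_ids, columns=samples)


def simulate_depths(
    truth: CommunityTruth,
    depth_scale: float,
    noise_cv: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scaftig depths across samples, plus a breadth-of-coverage table.

    The expected depth of scaftig t in sample s is
    ``depth_scale * abundance[genome(t), s]``.  Noise is a multiplicative
    log-normal factor with unit mean and coefficient of variation
    ``noise_cv``.  Coverage follows the Lander-Waterman expectation
    ``1 - exp(-depth)``.
    """
    if depth_scale <= 0:
        raise ValueError("simulate_depths: depth_scale must be > 0")
    if noise_cv < 0:
        raise ValueError("simulate_depths: noise_cv must be >= 0")
    if truth.abundance is None:
        raise ValueError("simulate_depths: truth has no abundance matrix")
    rng = np.random.default_rng(seed)
    ab = truth.abundance
    rows = []
    ids = []
    for sc in truth.scaftigs:
        expect = depth_scale * ab.loc[sc.genome_id].to_numpy()
        if noise_cv > 0:
            sigma2 = np.log1p(noise_cv**2)
            factor = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=len(expect)))
        else:
            factor = 1.0
        rows.append(expect * factor)
        ids.append(sc.id)
    depths = pd.DataFrame(rows, index=ids, columns=ab.columns)
    coverage = 1.0 - np.exp(-depths)
    return depths, coverage


def simulate_community(
    specs: list[GenomeSpec],
    n_samples: int,
    seed: int,
    scaftig_min: int = 1000,
    scaftig_max: int = 1500,
    depth_scale: float = 30.0,
    noise_cv: float = 0.1,
    mean_sigma: float = 1.0,
    sample_sigma: float = 1.0,
) -> tuple[CommunityTruth, pd.DataFrame, pd.DataFrame]:
    """Full community: genomes, scaftigs, abundance, depths, coverage.

    Returns ``(truth, depths, coverage)``.  Sub-seeds are derived from
    ``seed`` deterministically so each stage is independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(3 + len(specs)) >> 1]  # keep < 2^31
    genomes = dict(simulate_genomes(specs, seeds[0]))
    scaftigs: list[Scaftig] = []
    for i, (gid, seq) in enumerate(genomes.items()):
        scaftigs.extend(fragment_genome(seq, scaftig_min, scaftig_max, seeds[3 + i], genome_id=gid))
    abundance = simulate_abundance(list(genomes), n_samples, seeds[1], mean_sigma, sample_sigma)
    truth = CommunityTruth(genomes=genomes, scaftigs=scaftigs, abundance=abundance, seed=seed)
    depths, coverage = simulate_depths(truth, depth_scale, noise_cv, seeds[2])
    return truth, depths, coverage


def simulate_feature_tables(
    n_samples: int,
    n_kos: int,
    hierarchy_breadth: int,
    core_fraction: float,
    seed: int,
    n_functions: int = 20,
    presence_p: float = 0.5,
    presence_cutoff: float = 1e-7,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Per-sample KO abundance table plus a KO -> second-level-function map.

    A ``core_fraction`` share of KOs is present (abundance > cutoff) in
    every sample; the rest are present in each sample independently with
    probability ``presence_p``.  Each KO maps to 1..hierarchy_breadth
    functions drawn from a pool of ``n_functions``.
    """
    if not 0.0 <= core_fraction <= 1.0:
        raise ValueError("simulate_feature_tables: core_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    kos = [f"K{i:05d}" for i in range(n_kos)]
    samples = [f"sample_{i + 1}" for i in range(n_samples)]
    n_core = int(round(core_fraction * n_kos))
    present = np.zeros((n_kos, n_samples), dtype=bool)
    present[:n_core, :] = True
    present[n_core:, :] = rng.random((n_kos - n_core, n_samples)) < presence_p
    vals = np.where(present, rng.lognormal(0.0, 1.0, size=present.shape), 0.0)
    col_sums = vals.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    vals = vals / col_sums
    # relative abundances of present KOs sit far above the 1e-7 cutoff for
    # any table of this size; assert rather than silently violate the contract
    assert (vals[present] > presence_cutoff).all()
    table = pd.DataFrame(vals, index=kos, columns=samples)
    funcs = [f"F{i:02d}" for i in range(n_functions)]
    hierarchy = {
        ko: set(rng.choice(funcs, size=int(rng.integers(1, hierarchy_breadth + 1)), replace=False))
        for ko in kos
    }
    return table, hierarchy


def write_community(
    truth: CommunityTruth,
    depths: pd.DataFrame,
    coverage: pd.DataFrame,
    outdir: str | Path,
    params: dict | None = None,
) -> None:
    """Write scaftig FASTA, truth/depth/coverage TSVs and a JSON manifest."""
    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "scaftigs.fasta", [(s.id, s.sequence) for s in truth.scaftigs])
    pd.Series(truth.scaftig_origin, name="genome_id").rename_axis("scaftig_id").to_csv(
        outdir / "scaftig_origin.tsv", sep="\t"
    )
    depths.rename_axis("scaftig_id").to_csv(outdir / "depths.tsv", sep="\t")
    coverage.rename_axis("scaftig_id").to_csv(outdir / "coverage.tsv", sep="\t")
    truth.abundance.rename_axis("genome_id").to_csv(outdir / "abundance.tsv", sep="\t")
    manifest = {"seed": truth.seed, "n_genomes": len(truth.genomes),
                "n_scaftigs": len(truth.scaftigs), "params": params or {}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
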