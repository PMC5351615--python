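"""Synthetic RRBS study generator with known ground truth.

The generator emulates the structure of a paired primary/metastatic
bisulfite-sequencing study: an immortalised "normal" reference sample,
``n_pairs`` matched primary/metastatic samples (optionally with replicate
libraries), differentially methylated fragments (DMFs) planted either in
every pair (shared) or in a single pair (private), and an array-style
validation cohort whose probe beta values mirror the planted effects.

Methylation truth is assigned per fragment.  Background fragments draw
their level from a bimodal mixture concentrated near 0 and 1, the pattern
characteristic of somatic methylomes.  Each pair adds a small shared
baseline offset per fragment so that a primary sample resembles its own
metastatic partner more than any other sample.  Planted DMFs draw their
pre-shift baseline from the mixture component compatible with the effect
direction (hypermethylation events start low, hypomethylation events start
high), so the designed effect size survives clipping to [0, 1].

Read counts follow a negative-binomial coverage model with beta-binomial
methylated counts; both dispersions dial back to Poisson/binomial at 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .digest import digest_and_index
from .regions import Fragment, FragmentCatalog

TRUTH_FORMAT_VERSION = "epidriver-truth-v1"

_LEVEL_LO = 0.02  # headroom kept when sampling planted baselines
_LEVEL_HI = 0.98


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class StudyDesign:
    """Shape and sequencing depth of the simulated paired study.

    Defaults mirror the cell-line panel the pipeline targets: three
    primary/metastatic pairs, one normal reference, and duplicate libraries
    for the normal and the first primary sample.
    """

    n_pairs: int = 3
    include_normal: bool = True
    replicate_samples: tuple[str, ...] = ("normal", "P1")
    coverage_mean: float = 30.0
    dispersion: float = 0.1  # NB coverage: var = mu + dispersion * mu^2
    meth_dispersion: float = 0.05  # beta-binomial intra-class correlation
    pair_divergence: float = 0.05  # sd of per-(fragment, pair) baseline offsets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be > 0")
        if self.dispersion < 0 or self.meth_dispersion < 0:
            raise ConfigError("dispersions must be >= 0")
        known = set(self.sample_ids())
        unknown = set(self.replicate_samples) - known
        if unknown:
            raise ConfigError(f"replicate_samples not in design: {sorted(unknown)}")

    def pair_ids(self) -> list[str]:
        return [f"P{i}" for i in range(1, self.n_pairs + 1)]

    def sample_ids(self) -> list[str]:
        ids = ["normal"] if self.include_normal else []
        for i in range(1, self.n_pairs + 1):
            ids += [f"P{i}", f"M{i}"]
        return ids

    def library_ids(self) -> list[tuple[str, str]]:
        """(library_id, sample_id) for every sequencing library."""
        libs = [(s, s) for s in self.sample_ids()]
        libs += [(f"{s}-rep2", s) for s in self.replicate_samples]
        return libs


@dataclass(frozen=True)
class PlantedEffect:
    """One block of designed methylation changes.

    scope 'shared' shifts every metastatic sample by +/-delta relative to
    its primary; 'private' shifts a single pair.  ``step1_direction``, when
    set, additionally shifts all primaries relative to the normal sample by
    the same magnitude, creating a two-step progression pattern.
    """

    scope: str  # 'shared' | 'private'
    direction: str  # 'hyper' | 'hypo' (primary -> metastatic)
    delta: float
    n_fragments: int
    pair_id: str | None = None
    step1_direction: str | None = None

    def __post_init__(self) -> None:
        if self.scope not in ("shared", "private"):
            raise ConfigError(f"unknown planted scope: {self.scope}")
        if self.direction not in ("hyper", "hypo"):
            raise ConfigError(f"unknown direction: {self.direction}")
        if not (0 < self.delta <= 1):
            raise ConfigError("delta must be in (0, 1]")
        if self.scope == "private" and self.pair_id is None:
            raise ConfigError("private effect requires pair_id")
        if self.step1_direction not in (None, "hyper", "hypo"):
            raise ConfigError(f"unknown step1_direction: {self.step1_direction}")


@dataclass(frozen=True)
class CohortDesign:
    """Array-style validation cohort mirroring a tumor collection."""

    n_primary: int = 99
    n_metastatic: int = 359
    probe_offset: int = 0  # bases from the source fragment (0 = inside)
    beta_noise: float = 0.1
    n_decoys: int = 50
    decoy_gap: int = 10_001  # decoys sit at least this far from any DMF

    def __post_init__(self) -> None:
        if self.n_primary < 2 or self.n_metastatic < 2:
            raise ConfigError("cohort needs >= 2 samples per group")
        if abs(self.probe_offset) > 500:
            raise ConfigError(
                "matched probes must lie within 500 bp of the fragment"
            )


@dataclass
class TruthTable:
    """Ground truth: designed levels and planted-DMF labels.

    ``levels``: fragment_id x sample_id matrix of true methylation levels.
    ``labels``: one row per fragment with columns label ('background',
    'dmf_shared', 'dmf_private'), direction, delta_true, pair_id, pattern.
    """

    levels: pd.DataFrame
    labels: pd.DataFrame

    def planted(self, label: str | None = None) -> pd.DataFrame:
        out = self.labels[self.labels["label"] != "background"]
        if label is not None:
            out = out[out["label"] == label]
        return out


# ---------------------------------------------------------------------------
# genome generation


def _disrupt_ccgg(seq: np.ndarray, keep: set[int]) -> None:
    """Destroy CCGG occurrences not starting at a ``keep`` offset in place."""
    text = "".join(seq)
    start = 0
    while True:
        i = text.find("CCGG", start)
        if i < 0:
            break
        if i not in keep:
            seq[i + 2] = "T"  # CCGG -> CCTG; T cannot recreate a site
            text = text[: i + 2] + "T" + text[i + 3 :]
        start = i + 1


def generate_genome(
    n_chroms: int = 2,
    chrom_len: int = 200_000,
    ccgg_rate: float = 0.008,
    cgi_blocks: int = 5,
    seed: int = 0,
    cgi_len: int = 1000,
    island_ccgg_boost: float = 3.0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build a random genome with controlled MspI sites and CpG islands.

    Returns (sequences, island table).  All CCGG sites are injected at the
    requested per-base rate (natural occurrences are disrupted), so
    ``ccgg_rate=0`` yields a fragment-free genome and raises.  Islands are
    CpG-dense blocks with a boosted CCGG rate; their coordinates are
    returned as a BED-style frame.
    """
    if chrom_len < 1000:
        raise ConfigError("chrom_len must be >= 1000")
    rng = np.random.default_rng([11, seed])
    genome: dict[str, str] = {}
    islands: list[tuple[str, int, int, str]] = []
    bases = np.array(list("ACGT"))
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(bases, size=chrom_len, p=[0.3, 0.2, 0.2, 0.3])
        # non-overlapping islands with elevated CpG density
        island_starts: list[int] = []
        tries = 0
        while len(island_starts) < cgi_blocks and tries < 1000:
            s = int(rng.integers(0, chrom_len - cgi_len))
            tries += 1
            if all(abs(s - t) >= cgi_len + 100 for t in island_starts):
                island_starts.append(s)
        for k, s in enumerate(sorted(island_starts)):
            seq[s : s + cgi_len] = rng.choice(
                bases, size=cgi_len, p=[0.15, 0.35, 0.35, 0.15]
            )
            islands.append((chrom, s, s + cgi_len, f"{chrom}_CGI{k + 1}"))
        # choose CCGG positions: background rate everywhere, boosted in islands
        rate = np.full(chrom_len - 3, ccgg_rate)
        for ch, s, e, _name in islands:
            if ch == chrom:
                rate[s : max(s, e - 3)] = ccgg_rate * island_ccgg_boost
        hits = np.flatnonzero(rng.random(chrom_len - 3) < rate)
        keep: list[int] = []
        last = -10
        for h in hits:
            if h - last >= 4:
                keep.append(int(h))
                last = h
        _disrupt_ccgg(seq, set())  # remove natural sites first
        for h in keep:
            seq[h : h + 4] = list("CCGG")
        _disrupt_ccgg(seq, set(keep))  # sites created at island boundaries etc.
        genome[chrom] = "".join(seq)
    island_df = pd.DataFrame(islands, columns=["chrom", "start", "end", "name"])
    catalog = digest_and_index(genome)
    if len(catalog) == 0:
        raise DataError(
            "generated genome yields no 40-220 bp fragments; "
            f"increase ccgg_rate (got {ccgg_rate}) or chrom_len"
        )
    return genome, island_df


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# methylation truth


def _mixture_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal background levels: equal mixture of Beta(2,38) and Beta(38,2)."""
    low = rng.beta(2.0, 38.0, size=n)
    high = rng.beta(38.0, 2.0, size=n)
    pick_high = rng.random(n) < 0.5
    return np.where(pick_high, high, low)


def _directional_baseline(
    rng: np.random.Generator, shifts: Sequence[float]
) -> float:
    """Pre-shift baseline for a planted fragment.

    Drawn from the background mixture component compatible with the first
    designed shift (an upward shift starts from the low mode, a downward
    shift from the high mode — hypermethylation events arise at
    unmethylated loci and vice versa), then clamped into the interval
    where the baseline plus every cumulative shift stays inside
    [0.02, 0.98], so designed effect sizes survive without clipping.
    """
    cum = np.concatenate([[0.0], np.cumsum(shifts)])
    lo = _LEVEL_LO - cum.min()
    hi = _LEVEL_HI - cum.max()
    if lo > hi:
        raise ConfigError(f"planted shifts {list(shifts)} cannot fit in [0, 1]")
    first = next((s for s in shifts if s != 0.0), 0.0)
    if first > 0:
        draw = rng.beta(2.0, 38.0)
    elif first < 0:
        draw = rng.beta(38.0, 2.0)
    else:
        draw = rng.uniform(lo, hi)
    return float(min(max(draw, lo), hi))


def plan_methylation_states(
    catalog: FragmentCatalog,
    design: StudyDesign,
    planted: Sequence[PlantedEffect] = (),
    min_cpgs_planted: int = 2,
) -> TruthTable:
    """Assign true methylation levels to every fragment and sample.

    Planted effects are placed on distinct fragments with at least
    ``min_cpgs_planted`` CpGs (never fewer than 2, so the downstream
    coverage gate can pass).  Shifts are applied before the final clip to
    [0, 1]; baselines are chosen so clipping is not normally triggered.
    """
    rng = np.random.default_rng([1, design.seed])
    samples = design.sample_ids()
    pair_ids = design.pair_ids()
    frag_ids = [f.id for f in catalog]
    n = len(frag_ids)

    min_cpgs_planted = max(2, min_cpgs_planted)
    eligible = [f.id for f in catalog if f.n_cpgs >= min_cpgs_planted]
    n_requested = sum(p.n_fragments for p in planted)
    if n_requested > len(eligible):
        raise ConfigError(
            f"{n_requested} planted fragments requested but only "
            f"{len(eligible)} fragments have >= {min_cpgs_planted} CpGs"
        )
    for eff in planted:
        if eff.pair_id is not None and eff.pair_id not in pair_ids:
            raise ConfigError(f"unknown pair_id {eff.pair_id!r}")

    chosen = (
        list(rng.choice(eligible, size=n_requested, replace=False))
        if n_requested
        else []
    )

    baseline = pd.Series(_mixture_baseline(rng, n), index=frag_ids)
    # per-(fragment, pair) offsets shared by the pair's P and M samples
    pair_offset = {
        p: pd.Series(rng.normal(0.0, design.pair_divergence, size=n), index=frag_ids)
        for p in pair_ids
    }
    normal_offset = pd.Series(
        rng.normal(0.0, design.pair_divergence, size=n), index=frag_ids
    )

    # designed shifts per fragment: step1 (normal->primary), step2 (P->M, per pair)
    step1 = pd.Series(0.0, index=frag_ids)
    step2 = pd.DataFrame(0.0, index=frag_ids, columns=pair_ids)
    labels = pd.DataFrame(
        {
            "fragment_id": frag_ids,
            "label": "background",
            "direction": "",
            "delta_true": np.nan,
            "pair_id": "",
            "pattern": "",
        }
    ).set_index("fragment_id", drop=False)

    cursor = 0
    for eff in planted:
        ids = chosen[cursor : cursor + eff.n_fragments]
        cursor += eff.n_fragments
        s2 = eff.delta if eff.direction == "hyper" else -eff.delta
        s1 = 0.0
        if eff.step1_direction is not None:
            s1 = eff.delta if eff.step1_direction == "hyper" else -eff.delta
        for fid in ids:
            baseline.loc[fid] = _directional_baseline(rng, [s1, s2])
            if eff.step1_direction is not None:
                step1.loc[fid] = s1
            if eff.scope == "shared":
                step2.loc[fid, :] = s2
            else:
                step2.loc[fid, eff.pair_id] = s2
            labels.loc[fid, "label"] = f"dmf_{eff.scope}"
            labels.loc[fid, "direction"] = eff.direction
            labels.loc[fid, "delta_true"] = eff.delta
            labels.loc[fid, "pair_id"] = eff.pair_id or ""
            if eff.step1_direction is not None:
                labels.loc[fid, "pattern"] = f"{eff.step1_direction}-{eff.direction}"

    levels = pd.DataFrame(index=frag_ids, columns=samples, dtype=float)
    if design.include_normal:
        levels["normal"] = baseline + normal_offset
    for p in pair_ids:
        primary = baseline + pair_offset[p] + step1
        levels[p] = primary
        levels[p.replace("P", "M", 1)] = primary + step2[p]
    levels = levels.clip(0.0, 1.0)
    labels = labels.reset_index(drop=True)
    return TruthTable(levels=levels, labels=labels)


# ---------------------------------------------------------------------------
# count simulation


def _nb_coverage(
    rng: np.random.Generator, mean: float, dispersion: float, n: int
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def _beta_binomial(
    rng: np.random.Generator, cov: np.ndarray, level: np.ndarray, rho: float
) -> np.ndarray:
    meth = np.zeros_like(cov)
    inner = (level > 0) & (level < 1) & (cov > 0)
    if rho == 0:
        meth[inner] = rng.binomial(cov[inner], level[inner])
    else:
        a = level[inner] * (1 - rho) / rho
        b = (1 - level[inner]) * (1 - rho) / rho
        p = rng.beta(a, b)
        meth[inner] = rng.binomial(cov[inner], p)
    meth[(level >= 1) & (cov > 0)] = cov[(level >= 1) & (cov > 0)]
    return meth


def simulate_counts(
    truth: TruthTable,
    catalog: FragmentCatalog,
    design: StudyDesign,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Draw per-CpG read counts for every library of the design.

    Every CpG of a fragment shares that fragment's true level for the
    library's sample.  Replicate libraries are independent draws from the
    same truth.  Positions that receive zero coverage are omitted, as in
    real Bismark coverage output.  When ``out_dir`` is given, one
    ``<library>.cov`` file is written per library.
    """
    missing = set(f.id for f in catalog) - set(truth.levels.index)
    if missing:
        raise DataError(f"truth does not cover {len(missing)} catalog fragments")
    index = catalog.cpg_index()  # chrom, pos, fragment_id
    out: dict[str, pd.DataFrame] = {}
    for li, (lib_id, sample_id) in enumerate(design.library_ids()):
        rng = np.random.default_rng([2, design.seed, li])
        level = truth.levels.loc[index["fragment_id"], sample_id].to_numpy()
        cov = _nb_coverage(rng, design.coverage_mean, design.dispersion, len(index))
        meth = _beta_binomial(rng, cov, level, design.meth_dispersion)
        df = pd.DataFrame(
            {
                "chrom": index["chrom"],
                "pos": index["pos"],
                "meth": meth,
                "unmeth": cov - meth,
            }
        )
        df = df[cov > 0].reset_index(drop=True)
        out[lib_id] = df
        if out_dir is not None:
            write_coverage_file(df, Path(out_dir) / f"{lib_id}.cov")
    return out


def write_coverage_file(counts: pd.DataFrame, path: str | Path) -> None:
    """Write counts in Bismark coverage format (1-based inclusive)."""
    cov = counts["meth"] + counts["unmeth"]
    pct = np.where(cov > 0, 100.0 * counts["meth"] / cov.replace(0, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": counts["chrom"],
            "start": counts["pos"] + 1,
            "end": counts["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": counts["meth"],
            "unmeth": counts["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_sample_sheet(design: StudyDesign, cov_dir: str | Path, path: str | Path) -> None:
    """Write the sample sheet the pipeline consumes.

    Columns: sample_id, role, pair_id, replicate_of, path.  Coverage paths
    are stored as given in ``cov_dir``; relative paths are resolved
    against the sheet's own directory at load time.
    """
    rows = []
    for lib_id, sample_id in design.library_ids():
        if sample_id == "normal":
            role, pair = "normal", ""
        elif sample_id.startswith("P"):
            role, pair = "primary", sample_id
        else:
            role, pair = "metastatic", sample_id.replace("M", "P", 1)
        replicate_of = sample_id if lib_id != sample_id else ""
        rows.append(
            (lib_id, role, pair, replicate_of, str(Path(cov_dir) / f"{lib_id}.cov"))
        )
    pd.DataFrame(
        rows, columns=["sample_id", "role", "pair_id", "replicate_of", "path"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort + expression


def _probe_position(frag: Fragment, offset: int) -> int:
    if offset == 0:
        return frag.interval.midpoint
    if offset > 0:
        return frag.end - 1 + offset
    return frag.start + offset


def simulate_cohort(
    truth: TruthTable,
    cohort: CohortDesign,
    dmf_subset: Sequence[str],
    catalog: FragmentCatalog,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an array-style cohort mirroring the planted DMFs.

    Returns (probes, betas, groups): one matched probe per fragment in
    ``dmf_subset`` at the designed offset, plus decoy probes far from every
    DMF whose two groups share one level.  Betas are group truth plus
    Gaussian noise, clipped to [0, 1].
    """
    rng = np.random.default_rng([3, seed])
    frags = catalog.by_id()
    unknown = [f for f in dmf_subset if f not in frags]
    if unknown:
        raise DataError(f"dmf_subset fragments not in catalog: {unknown[:5]}")
    pair_ids = [c for c in truth.levels.columns if c.startswith("P")]
    met_ids = [p.replace("P", "M", 1) for p in pair_ids]

    probe_rows = []
    prim_level = []
    met_level = []
    for fid in dmf_subset:
        frag = frags[fid]
        probe_rows.append(
            (
                f"probe_{fid}",
                frag.chrom,
                _probe_position(frag, cohort.probe_offset),
                fid,
                False,
            )
        )
        prim_level.append(truth.levels.loc[fid, pair_ids].mean())
        met_level.append(truth.levels.loc[fid, met_ids].mean())
    # decoys: beyond decoy_gap of any catalog fragment, same level in both groups
    last_end = max(f.end for f in catalog.fragments)
    chrom = catalog.fragments[0].chrom
    decoy_levels = _mixture_baseline(rng, cohort.n_decoys)
    for k in range(cohort.n_decoys):
        probe_rows.append(
            (
                f"decoy_{k + 1}",
                chrom,
                last_end + cohort.decoy_gap + 100 * k,
                "",
                True,
            )
        )
        prim_level.append(decoy_levels[k])
        met_level.append(decoy_levels[k])

    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "source_fragment", "decoy"]
    )
    sample_ids = [f"C_P{i:03d}" for i in range(1, cohort.n_primary + 1)] + [
        f"C_M{i:03d}" for i in range(1, cohort.n_metastatic + 1)
    ]
    groups = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["primary"] * cohort.n_primary
            + ["metastatic"] * cohort.n_metastatic,
        }
    )
    true_mat = np.empty((len(probes), len(sample_ids)))
    true_mat[:, : cohort.n_primary] = np.asarray(prim_level)[:, None]
    true_mat[:, cohort.n_primary :] = np.asarray(met_level)[:, None]
    noise = (
        rng.normal(0.0, cohort.beta_noise, size=true_mat.shape)
        if cohort.beta_noise > 0
        else 0.0
    )
    betas = pd.DataFrame(
        np.clip(true_mat + noise, 0.0, 1.0),
        index=probes["probe_id"],
        columns=sample_ids,
    )
    return probes, betas, groups


def simulate_expression(
    betas: pd.DataFrame,
    probes: pd.DataFrame,
    gene_links: Sequence[tuple[str, str, int]],
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression values linked monotonically to probe betas.

    ``gene_links`` holds (gene_id, source fragment id, sign); expression is
    sign * beta plus Gaussian noise, so at zero noise the Spearman rank
    correlation with the probe beta equals the designed sign exactly.
    Returns a gene x sample table.
    """
    rng = np.random.default_rng([4, seed])
    by_fragment = probes[~probes["decoy"]].set_index("source_fragment")["probe_id"]
    rows = {}
    for gene_id, fid, sign in gene_links:
        if fid not in by_fragment.index:
            raise DataError(f"gene link {gene_id}: no probe for fragment {fid}")
        if sign not in (1, -1):
            raise DataError(f"gene link {gene_id}: sign must be +1 or -1")
        beta = betas.loc[by_fragment[fid]].to_numpy(dtype=float)
        expr = sign * beta
        if noise > 0:
            expr = expr + rng.normal(0.0, noise, size=expr.shape)
        rows[gene_id] = expr
    return pd.DataFrame(rows, index=betas.columns).T


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: TruthTable, levels_path: str | Path, labels_path: str | Path) -> None:
    """Write truth tables as TSV with a versioned header line."""
    for path, df, index in (
        (levels_path, truth.levels, True),
        (labels_path, truth.labels, False),
    ):
        with open(path, "w") as fh:
            fh.write(f"# {TRUTH_FORMAT_VERSION}\n")
            df.to_csv(
                fh, sep="\t", index=index, index_label="fragment_id" if index else None
            )


def read_truth(levels_path: str | Path, labels_path: str | Path) -> TruthTable:
    for path in (levels_path, labels_path):
        with open(path) as fh:
            header = fh.readline().strip()
        if header != f"# {TRUTH_FORMAT_VERSION}":
            raise DataError(f"{path}: not a {TRUTH_FORMAT_VERSION} file")
    levels = pd.read_csv(levels_path, sep="\t", comment="#", index_col="fragment_id")
    levels.index.name = None
    labels = pd.read_csv(
        labels_path, sep="\t", comment="#", keep_default_na=False,
        dtype={"pair_id": str, "pattern": str, "direction": str},
    )
    labels["delta_true"] = pd.to_numeric(labels["delta_true"], errors="coerce")
    return TruthTable(levels=levels, labels=labels)
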