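"""Seeded synthetic-data generators with ground truth for every pipeline stage.

Everything downstream of raw data acquisition is exercised on the outputs of
this module: explant-like multi-channel images with per-nucleus latent
positivity labels, genome fixtures whose nearest-TSS association counts are
constructed (and verified) to hit requested per-cluster totals, peak
sequences with implanted composite motifs, and DE / qPCR / densitometry
tables. All generators are pure functions of (params, seed).

Named fixture profiles package the study conditions used by the figure
presets and acceptance checks:

* ``fig1c`` — the stagewise ground-truth double-positive profile
  (1.00, 0.79, 0.69, 0.34, 0.14 for stages 10.5 → 15);
* ``fig4`` / ``fig4e`` — peak-wise and gene-wise cluster association counts
  (5300 peaks / 596 NPB-associated; 2114 NPB genes / 400 peaked);
* ``fig6`` — two peak sets with 3500 of 5300 border-set peaks shared;
* ``fig6motif`` — shared-peak sequences with the composite Oct4-Sox2
  consensus implanted in 25% of sequences;
* ``fig1d`` — densitometry series decreasing to 20% of baseline by stage 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imagequant import ImageStack, PackingError
from .motifscan import IUPAC, OCT4_SOX2_CONSENSUS, reverse_complement
from .peak_annotation import GenomeAnnotation, PeakSet, nearest_tss

# ---------------------------------------------------------------------------
# explant images


@dataclass
class ExplantImageParams:
    """Geometry, latent label fractions and intensity model of one synthetic
    explant image. ``frac_double_given_pax3`` is the ground-truth
    colocalization statistic; ``frac_sox3_only`` is P(Sox3+ | pax3−)."""

    width: int = 512
    height: int = 512
    n_nuclei: int = 300
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 0.8
    frac_pax3: float = 0.5
    frac_double_given_pax3: float = 0.79
    frac_sox3_only: float = 0.3
    signal_level: float = 180.0
    background_level: float = 25.0
    noise_sd: float = 2.0
    max_overlap_frac: float = 0.0
    separation_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_pax3", "frac_double_given_pax3", "frac_sox3_only", "max_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.nucleus_radius_mean < 3.0:
            raise ValueError("nucleus_radius_mean < 3 px cannot guarantee >= 20 px discs")


@dataclass
class ExplantTruth:
    """Latent generator state for one explant image."""

    centers: np.ndarray  # (n, 2) row, col
    radii: np.ndarray
    pax3: np.ndarray  # bool
    sox3: np.ndarray  # bool
    true_double_fraction: float


def _circle_overlap_area(r1: float, r2: float, d: float) -> float:
    if d >= r1 + r2:
        return 0.0
    rmin, rmax = min(r1, r2), max(r1, r2)
    if d <= rmax - rmin:
        return np.pi * rmin**2
    a1 = r1**2 * np.arccos(np.clip((d**2 + r1**2 - r2**2) / (2 * d * r1), -1, 1))
    a2 = r2**2 * np.arccos(np.clip((d**2 + r2**2 - r1**2) / (2 * d * r2), -1, 1))
    k = 0.5 * np.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return a1 + a2 - 2 * k


def _pack_nuclei(p: ExplantImageParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = 400 * p.n_nuclei
    tries = 0
    while len(centers) < p.n_nuclei:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {p.n_nuclei} nuclei of mean radius "
                f"{p.nucleus_radius_mean} px in a {p.width}x{p.height} image after "
                f"{max_tries} attempts; reduce density or raise max_overlap_frac"
            )
        tries += 1
        r = float(np.clip(rng.normal(p.nucleus_radius_mean, p.nucleus_radius_sd), 3.0, None))
        row = rng.uniform(r, p.height - r)
        col = rng.uniform(r, p.width - r)
        ok = True
        for (cr, cc), orad in zip(centers, radii):
            d = float(np.hypot(row - cr, col - cc))
            if p.max_overlap_frac <= 0.0:
                # resolvable-monolayer regime: discs never touch, with a
                # pixel-safe gap so 8-connected components stay separate
                if d < r + orad + p.separation_px:
                    ok = False
                    break
            elif _circle_overlap_area(r, orad, d) > p.max_overlap_frac * np.pi * min(r, orad) ** 2:
                ok = False
                break
        if ok:
            centers.append((row, col))
            radii.append(r)
    return np.asarray(centers), np.asarray(radii)


def make_explant_image(params: ExplantImageParams) -> tuple[ImageStack, ExplantTruth]:
    """Generate one 3-channel explant image plus its latent ground truth.

    Nuclei are filled discs (>= 20 px) bright in DAPI; pax3 / Sox3 signal is
    painted inside nuclei according to the latent positivity labels; Gaussian
    noise of the given sd is added on top of the background level. The same
    params (including seed) always produce the identical image.
    """
    rng = np.random.default_rng(params.seed)
    centers, radii = _pack_nuclei(params, rng)

    pax3 = rng.random(params.n_nuclei) < params.frac_pax3
    sox3 = np.where(
        pax3,
        rng.random(params.n_nuclei) < params.frac_double_given_pax3,
        rng.random(params.n_nuclei) < params.frac_sox3_only,
    )
    n_pax3 = int(pax3.sum())
    true_frac = float((pax3 & sox3).sum() / n_pax3) if n_pax3 else float("nan")

    shape = (params.height, params.width)
    channels = {c: np.zeros(shape) for c in ("dapi", "sox3", "pax3")}
    for (row, col), r, is_p, is_s in zip(centers, radii, pax3, sox3):
        r0, r1 = max(0, int(np.floor(row - r))), min(params.height, int(np.ceil(row + r)) + 1)
        c0, c1 = max(0, int(np.floor(col - r))), min(params.width, int(np.ceil(col + r)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disc = (yy - row) ** 2 + (xx - col) ** 2 <= r**2
        channels["dapi"][r0:r1, c0:c1][disc] = params.signal_level
        if is_p:
            channels["pax3"][r0:r1, c0:c1][disc] = params.signal_level
        if is_s:
            channels["sox3"][r0:r1, c0:c1][disc] = params.signal_level

    for name in ("dapi", "sox3", "pax3"):
        img = channels[name] + params.background_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, shape)
        channels[name] = np.clip(np.round(img), 0, 255).astype(np.uint16)

    stack = ImageStack(**channels)
    return stack, ExplantTruth(centers, radii, pax3, sox3, true_frac)


#: ground-truth double-positive fraction per developmental stage
FIG1C_PROFILE: dict[str, float] = {
    "10.5": 1.00,
    "11.5": 0.79,
    "12.5": 0.69,
    "13": 0.34,
    "15": 0.14,
}


def explant_params_for_stage(stage: str, seed: int = 0, **overrides) -> ExplantImageParams:
    """The 'fig1c' profile entry for a developmental stage."""
    if stage not in FIG1C_PROFILE:
        raise KeyError(f"unknown stage {stage!r}; profile has {sorted(FIG1C_PROFILE)}")
    return ExplantImageParams(
        frac_double_given_pax3=FIG1C_PROFILE[stage], seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# genome fixtures


@dataclass
class ChipFixtureParams:
    """Genome fixture targets.

    Exactly one of ``target_association_counts`` (peak-wise: how many peaks
    have their nearest TSS in each cluster) or ``target_genes_with_peak``
    (gene-wise: how many distinct cluster genes carry >= 1 peak) constrains
    the construction; remaining peaks go to filler genes outside all
    clusters. ``n_peaks_b_shared`` / ``n_peaks_b_only`` optionally emit a
    second peak set overlapping the first on exactly the shared count.
    """

    n_genes_per_cluster: dict[str, int] = field(default_factory=dict)
    n_filler_genes: int = 1000
    n_peaks: int = 1000
    target_association_counts: dict[str, int] | None = None
    target_genes_with_peak: dict[str, int] | None = None
    n_peaks_b_shared: int | None = None
    n_peaks_b_only: int = 0
    tss_spacing: int = 10_000
    n_chroms: int = 4
    peak_width: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        targets = self.target_association_counts or self.target_genes_with_peak or {}
        if self.target_association_counts and self.target_genes_with_peak:
            raise ValueError("give only one of peak-wise / gene-wise targets")
        if sum(targets.values()) > self.n_peaks:
            raise ValueError("sum of target counts exceeds n_peaks")
        for name, count in targets.items():
            n_genes = self.n_genes_per_cluster.get(name, 0)
            if n_genes < 1:
                raise ValueError(f"cluster {name!r} in targets has no genes")
            if self.target_genes_with_peak and count > n_genes:
                raise ValueError(f"cluster {name!r}: {count} peaked genes > {n_genes} genes")
        if self.n_peaks_b_shared is not None and self.n_peaks_b_shared > self.n_peaks:
            raise ValueError("n_peaks_b_shared exceeds n_peaks")
        if self.peak_width % 2:
            raise ValueError("peak_width must be even")


@dataclass
class ChipFixture:
    genes: GenomeAnnotation
    peaks: PeakSet
    clusters: dict[str, list[str]]
    truth: "ChipTruth"
    peaks_b: PeakSet | None = None


@dataclass
class ChipTruth:
    """Intended cluster per peak (None for filler-targeted peaks)."""

    peak_cluster: dict[str, str | None]
    gene_cluster: dict[str, str]


def _place_genes(p: ChipFixtureParams, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, str]]:
    gene_ids, gene_cluster = [], {}
    for cluster, n in p.n_genes_per_cluster.items():
        for i in range(n):
            gid = f"{cluster}_g{i:05d}"
            gene_ids.append(gid)
            gene_cluster[gid] = cluster
    gene_ids += [f"oth_g{i:05d}" for i in range(p.n_filler_genes)]
    order = rng.permutation(len(gene_ids))
    jitter = p.tss_spacing // 8
    rows = []
    per_chrom = int(np.ceil(len(gene_ids) / p.n_chroms))
    for slot, gi in enumerate(order):
        chrom = f"chr{slot // per_chrom + 1}"
        rank = slot % per_chrom
        tss = p.tss_spacing * (rank + 1) + int(rng.integers(-jitter, jitter + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((gene_ids[gi], chrom, strand, tss))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])
    return genes, gene_cluster


def _peak_near_gene(gene_row, p: ChipFixtureParams, rng: np.random.Generator) -> tuple[str, int, int]:
    offset = int(rng.integers(-p.tss_spacing // 4, p.tss_spacing // 4 + 1))
    ref = int(gene_row.tss) + offset
    start = max(0, ref - p.peak_width // 2)
    return gene_row.chrom, start, start + p.peak_width


def make_chip_fixture(params: ChipFixtureParams, max_retries: int = 5) -> ChipFixture:
    """Generate annotation + peaks hitting the requested association targets.

    TSSs are placed on a regular grid (spacing ``tss_spacing``, jitter
    <= spacing/8) so that a peak centred within spacing/4 of a TSS is
    unambiguously nearest to it. After placement the fixture is verified by
    running :func:`nearest_tss` and counting; placement is retried on
    violation and an error raised if the targets remain unsatisfied.
    """
    rng = np.random.default_rng(params.seed)
    last_err = None
    for _ in range(max_retries):
        genes_df, gene_cluster = _place_genes(params, rng)
        gene_rows = {g.gene_id: g for g in genes_df.itertuples(index=False)}
        by_cluster: dict[str, list[str]] = {}
        for gid, cl in gene_cluster.items():
            by_cluster.setdefault(cl, []).append(gid)
        filler = [g for g in genes_df["gene_id"] if g not in gene_cluster]

        target_genes: list[str] = []
        peak_cluster: list[str | None] = []
        if params.target_association_counts:
            for cl, count in params.target_association_counts.items():
                chosen = rng.choice(by_cluster[cl], size=count, replace=True)
                target_genes += list(chosen)
                peak_cluster += [cl] * count
        elif params.target_genes_with_peak:
            for cl, count in params.target_genes_with_peak.items():
                chosen = rng.choice(by_cluster[cl], size=count, replace=False)
                target_genes += list(chosen)
                peak_cluster += [cl] * count
        n_filler_peaks = params.n_peaks - len(target_genes)
        if n_filler_peaks > 0:
            if not filler:
                raise ValueError("fixture needs filler genes for unassociated peaks")
            # distinct host genes when possible: peaks near distinct grid TSSs
            # can never overlap each other, which keeps two-set overlap counts
            # exactly at the requested values
            chosen = rng.choice(filler, size=n_filler_peaks, replace=len(filler) < n_filler_peaks)
            target_genes += list(chosen)
            peak_cluster += [None] * n_filler_peaks

        peak_rows = []
        for i, gid in enumerate(target_genes):
            chrom, start, end = _peak_near_gene(gene_rows[gid], params, rng)
            peak_rows.append((f"peak_{i:05d}", chrom, start, end))
        peaks = PeakSet(pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"]))
        annotation = GenomeAnnotation(genes_df)

        assoc = nearest_tss(peaks, annotation)
        assoc_cluster = assoc["gene_id"].map(gene_cluster)
        ok = True
        if params.target_association_counts:
            counts = assoc_cluster.value_counts()
            for cl, want in params.target_association_counts.items():
                if int(counts.get(cl, 0)) != want:
                    ok = False
        elif params.target_genes_with_peak:
            peaked = assoc.dropna(subset=["gene_id"])
            for cl, want in params.target_genes_with_peak.items():
                got = len(set(peaked["gene_id"]) & set(by_cluster[cl]))
                if got != want:
                    ok = False
        if not ok:
            last_err = "nearest-TSS verification failed"
            continue

        peaks_b = None
        if params.n_peaks_b_shared is not None:
            pk = peaks.peaks
            shared_idx = rng.choice(len(pk), size=params.n_peaks_b_shared, replace=False)
            rows_b = []
            for j, i in enumerate(sorted(shared_idx)):
                shift = int(rng.integers(-params.peak_width // 3, params.peak_width // 3 + 1))
                start = max(0, int(pk.iloc[i]["start"]) + shift)
                rows_b.append((f"bpeak_{j:05d}", pk.iloc[i]["chrom"], start, start + params.peak_width))
            # B-only peaks sit midway between TSSs, clear of every A peak
            lo = int(0.30 * params.tss_spacing)
            hi = int(0.42 * params.tss_spacing)
            hosts = rng.choice(genes_df["gene_id"], size=params.n_peaks_b_only, replace=False)
            for j, gid in enumerate(hosts, start=len(rows_b)):
                g = gene_rows[gid]
                ref = int(g.tss) + int(rng.integers(lo, hi + 1))
                start = ref - params.peak_width // 2
                rows_b.append((f"bpeak_{j:05d}", g.chrom, start, start + params.peak_width))
            peaks_b = PeakSet(pd.DataFrame(rows_b, columns=["peak_id", "chrom", "start", "end"]))

        truth = ChipTruth(
            peak_cluster={f"peak_{i:05d}": cl for i, cl in enumerate(peak_cluster)},
            gene_cluster=gene_cluster,
        )
        return ChipFixture(annotation, peaks, by_cluster, truth, peaks_b)
    raise RuntimeError(f"fixture generation failed after {max_retries} retries: {last_err}")


_CLUSTER_SIZES = {"NPB": 2114, "blastula": 1500, "NC": 1000, "C10": 3000}

CHIP_PROFILES: dict[str, ChipFixtureParams] = {
    # peak-wise association counts (596 / 5300 = 11% border-cluster peaks);
    # non-border counts are chosen consistent with the gene-wise coverage of
    # those clusters (~10% NC, 8% blastula, 4% C10); filler background is
    # genome-scale for the allotetraploid annotation
    "fig4": ChipFixtureParams(
        n_genes_per_cluster=dict(_CLUSTER_SIZES),
        n_filler_genes=45000,
        n_peaks=5300,
        target_association_counts={"NPB": 596, "blastula": 125, "NC": 105, "C10": 122},
        seed=11,
    ),
    # gene-wise counts (400 / 2114 = 19% border genes; 10% NC, 8% blastula, 4% C10)
    "fig4e": ChipFixtureParams(
        n_genes_per_cluster=dict(_CLUSTER_SIZES),
        n_filler_genes=45000,
        n_peaks=5300,
        target_genes_with_peak={"NPB": 400, "NC": 100, "blastula": 120, "C10": 120},
        seed=19,
    ),
    # two-set overlap, 3500 / 5300 = 66% of the border set shared
    "fig6": ChipFixtureParams(
        n_genes_per_cluster={},
        n_filler_genes=9800,
        n_peaks=5300,
        n_peaks_b_shared=3500,
        n_peaks_b_only=4500,
        seed=66,
    ),
}


def chip_fixture_profile(name: str, seed: int | None = None) -> ChipFixtureParams:
    """A named, versioned fixture parameter set (optionally reseeded)."""
    if name not in CHIP_PROFILES:
        raise KeyError(f"unknown profile {name!r}; have {sorted(CHIP_PROFILES)}")
    params = CHIP_PROFILES[name]
    return replace(params, seed=seed) if seed is not None else replace(params)


# ---------------------------------------------------------------------------
# peak sequences with implanted motifs


@dataclass
class SequenceTruth:
    implanted: dict[str, bool]
    positions: dict[str, int]
    strands: dict[str, str]
    sites: dict[str, str]


#: shared-peak motif incidence of the packaged profile
FIG6_MOTIF_IMPLANT_PROB = 0.25


def make_peak_sequences(
    n_seqs: int,
    length: int,
    implant_prob: float,
    motif: str = OCT4_SOX2_CONSENSUS,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> tuple[dict[str, str], SequenceTruth]:
    """Random background sequences, a fraction carrying one exact consensus.

    Background bases are i.i.d. (uniform by default). Implant-flagged
    sequences carry one realization of the IUPAC consensus (each ambiguous
    letter resolved uniformly at random) at a uniform random position and
    strand; string search therefore finds the site verbatim in 100% of
    flagged sequences.
    """
    if not 0.0 <= implant_prob <= 1.0:
        raise ValueError("implant_prob must be in [0, 1]")
    if length < len(motif):
        raise ValueError(f"sequence length {length} < motif length {len(motif)}")
    for letter in motif.upper():
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r} in motif")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    seqs: dict[str, str] = {}
    truth = SequenceTruth({}, {}, {}, {})
    for i in range(n_seqs):
        sid = f"seq_{i:05d}"
        seq = list(rng.choice(bases, size=length, p=bg))
        implant = bool(rng.random() < implant_prob)
        truth.implanted[sid] = implant
        if implant:
            site = "".join(rng.choice(list(IUPAC[c])) for c in motif.upper())
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else reverse_complement(site)
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos : pos + len(motif)] = list(inserted)
            truth.positions[sid] = pos
            truth.strands[sid] = strand
            truth.sites[sid] = site
        seqs[sid] = "".join(seq)
    return seqs, truth


# ---------------------------------------------------------------------------
# tables


def make_de_table(
    n_genes: int,
    frac_de: float = 0.1,
    lfc_effect: float = 3.0,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    lfc_se: float = 0.3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """DE result table with spiked effects.

    Null genes draw log2FC ~ N(0, se); DE genes draw N(effect, se). p-values
    come from the implied z-test and padj from BH, so padj is in [0, 1] and
    decreases monotonically with |effect|. Returns (table, true DE flags).
    """
    from scipy import stats as sps

    from .enrichment import bh_adjust

    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length mismatch")
    is_de = rng.random(n_genes) < frac_de
    lfc = rng.normal(0.0, lfc_se, n_genes) + np.where(is_de, lfc_effect, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(lfc) / lfc_se)
    table = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "pvalue": p, "padj": bh_adjust(p)}
    )
    return table, is_de


def make_ct_table(
    true_log2_fold: dict[tuple[str, str], float],
    control_condition: str = "wild_type",
    reference_gene: str = "odc",
    n_replicates: int = 3,
    base_ct: float = 24.0,
    ref_ct: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT-value table realizing given per-(gene, condition) fold changes.

    ``true_log2_fold[(gene, condition)]`` is log2 of the intended fold change
    relative to the control condition (control itself is implicitly 0).
    With zero noise the downstream ΔΔCT fold changes equal 2**true exactly.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for g, _ in true_log2_fold})
    conditions = sorted({c for _, c in true_log2_fold} | {control_condition})
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            rows.append((sample, cond, reference_gene, ref_ct + rng.normal(0, noise_sd), rep))
            for gene in genes:
                lfc = true_log2_fold.get((gene, cond), 0.0)
                ct = base_ct - lfc + rng.normal(0, noise_sd)
                rows.append((sample, cond, gene, ct, rep))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct", "replicate"])


#: stagewise true normalized Sox3/actin ratio (baseline stage 9)
FIG1D_PROFILE: dict[int, float] = {9: 1.0, 11: 1.25, 13: 0.55, 15: 0.2}


def make_densitometry_series(
    profile: dict[int, float] | None = None,
    n_replicates: int = 3,
    control_signal: float = 1000.0,
    base_ratio: float = 0.8,
    noise_sd: float = 0.0,
    condition: str = "NPB",
    seed: int = 0,
) -> pd.DataFrame:
    """Densitometry lanes whose normalized ratios follow ``profile``.

    ``profile`` maps stage -> true ratio relative to the baseline (first)
    stage; the default follows the stagewise Sox3/actin series with a
    stage-15 value of 0.2 (an 80% decrease). Multiplicative lognormal-ish
    noise of sd ``noise_sd`` (relative) is applied to the signal lane.
    """
    profile = FIG1D_PROFILE if profile is None else profile
    rng = np.random.default_rng(seed)
    rows = []
    for stage, ratio in profile.items():
        for rep in range(1, n_replicates + 1):
            noise = 1.0 + rng.normal(0, noise_sd) if noise_sd > 0 else 1.0
            signal = ratio * base_ratio * control_signal * noise
            rows.append((stage, condition, signal, control_signal, rep))
    return pd.DataFrame(rows, columns=["stage", "condition", "signal", "control_signal", "replicate"])
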