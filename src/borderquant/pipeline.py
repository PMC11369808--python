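"""Orchestration: figure-keyed presets, end-to-end runs, and run manifests.

Presets (``fig1c``, ``fig4``, ``fig4e``, ``fig6a``, ``fig6motif``, ``fig1d``)
tie the synthetic generators to the quantification stages with the packaged
study-condition profiles, and write their outputs plus a manifest recording
parameters, content hashes and versions. A preset run is byte-identical to
executing the equivalent stage calls manually with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import cluster_enrichment, forest_data
from .imagequant import (
    ColocConfig,
    call_nuclei,
    colocalization_fraction,
    sample_regions,
    summarize_stages,
)
from .motifscan import OCT4_SOX2_CONSENSUS, motif_incidence, pwm_from_iupac
from .peak_annotation import nearest_tss, shared_peaks
from .quant_stats import normalize_blot
from .synthetic_data import (
    FIG1C_PROFILE,
    FIG6_MOTIF_IMPLANT_PROB,
    chip_fixture_profile,
    explant_params_for_stage,
    make_chip_fixture,
    make_densitometry_series,
    make_explant_image,
    make_peak_sequences,
)

logger = logging.getLogger(__name__)

#: default batch layout: 3 biological replicates x 2 explants, 3 regions each
N_EXPLANTS_PER_STAGE = 6
N_REGIONS_PER_EXPLANT = 3
CELLS_PER_REGION = 50


@dataclass
class RunConfig:
    stages: list[dict]
    seed: int = 0
    outdir: str = "borderquant_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty stage list")
        for s in self.stages:
            if "name" not in s:
                raise ValueError(f"stage without a name: {s}")
            if s["name"] not in PRESETS:
                raise ValueError(f"unknown stage {s['name']!r}; have {sorted(PRESETS)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Writer:
    """Records every file written so the manifest is complete."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []

    def csv(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        self.files.append(path)
        return path

    def json(self, name: str, obj) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        self.files.append(path)
        return path


# ---------------------------------------------------------------------------
# preset computations (pure; file writing is separate)


def colocalization_profile(
    stages: list[str] | None = None,
    seed: int = 0,
    n_explants: int = N_EXPLANTS_PER_STAGE,
    n_regions: int = N_REGIONS_PER_EXPLANT,
    cells_per_region: int = CELLS_PER_REGION,
    n_nuclei: int = 300,
    cfg: ColocConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full image pipeline over the stagewise ground-truth profile.

    Per stage, ``n_explants`` synthetic explants are generated, nuclei called,
    ``n_regions`` regions of ``cells_per_region`` nuclei sampled per explant
    (18 regions per stage in the default layout), and the double-positive
    fraction computed per region. Returns (per-region table, stage summary).
    """
    stages = list(FIG1C_PROFILE) if stages is None else stages
    rows = []
    by_stage: dict[str, list[float]] = {}
    for si, stage in enumerate(stages):
        for e in range(n_explants):
            img_seed = seed + 1000 * si + e
            params = explant_params_for_stage(stage, seed=img_seed, n_nuclei=n_nuclei)
            stack, truth = make_explant_image(params)
            nuclei = call_nuclei(stack, cfg)
            regions = sample_regions(nuclei, n_regions, cells_per_region, seed=img_seed + 500_000)
            res = colocalization_fraction(nuclei, regions)
            for r in res.itertuples(index=False):
                rows.append(dict(stage=stage, explant=e, true_fraction=truth.true_double_fraction,
                                 **r._asdict()))
                by_stage.setdefault(stage, []).append(r.fraction)
    per_region = pd.DataFrame(rows)
    summary = summarize_stages(by_stage)
    return per_region, summary


def cluster_enrichment_run(profile: str, seed: int | None = None) -> pd.DataFrame:
    """Chip fixture -> nearest-TSS association -> per-cluster enrichment."""
    fixture = make_chip_fixture(chip_fixture_profile(profile, seed))
    assoc = nearest_tss(fixture.peaks, fixture.genes)
    universe = list(fixture.genes.genes["gene_id"])
    return cluster_enrichment(assoc, fixture.clusters, universe)


def shared_peaks_run(seed: int | None = None, min_overlap: int = 1) -> dict:
    fixture = make_chip_fixture(chip_fixture_profile("fig6", seed))
    return shared_peaks(fixture.peaks, fixture.peaks_b, min_overlap=min_overlap)


def motif_incidence_run(
    seed: int = 25,
    n_seqs: int = 1000,
    length: int = 200,
    implant_prob: float = FIG6_MOTIF_IMPLANT_PROB,
    pvalue_threshold: float = 1e-4,
) -> dict:
    seqs, truth = make_peak_sequences(n_seqs, length, implant_prob, seed=seed)
    pwm = pwm_from_iupac(OCT4_SOX2_CONSENSUS)
    result = motif_incidence(seqs, pwm, pvalue_threshold)
    result["true_implant_fraction"] = float(np.mean(list(truth.implanted.values())))
    return result


def blot_run(seed: int = 0, noise_sd: float = 0.0) -> pd.DataFrame:
    blot = make_densitometry_series(noise_sd=noise_sd, seed=seed)
    return normalize_blot(blot, baseline_stage=9)


# ---------------------------------------------------------------------------
# preset registry and runner


def _preset_fig1c(seed: int, w: _Writer, params: dict) -> None:
    per_region, summary = colocalization_profile(seed=seed, **params)
    w.csv("fig1c_regions.csv", per_region)
    w.csv("fig1c_summary.csv", summary)


def _preset_cluster(profile: str):
    def run(seed: int, w: _Writer, params: dict) -> None:
        result = cluster_enrichment_run(profile, seed=params.get("seed"))
        w.csv(f"{profile}_enrichment.csv", result)
        w.csv(f"{profile}_forest.csv", forest_data(result))

    return run


def _preset_fig6a(seed: int, w: _Writer, params: dict) -> None:
    w.json("fig6a_overlap.json", shared_peaks_run(seed=params.get("seed")))


def _preset_fig6motif(seed: int, w: _Writer, params: dict) -> None:
    w.json("fig6motif_incidence.json", motif_incidence_run(seed=seed, **params))


def _preset_fig1d(seed: int, w: _Writer, params: dict) -> None:
    w.csv("fig1d_blot.csv", blot_run(seed=seed, **params))


PRESETS = {
    "fig1c": _preset_fig1c,
    "fig4": _preset_cluster("fig4"),
    "fig4e": _preset_cluster("fig4e"),
    "fig6a": _preset_fig6a,
    "fig6motif": _preset_fig6motif,
    "fig1d": _preset_fig1d,
}


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write a run manifest.

    Every output file appears in the manifest with a sha256 content hash;
    re-running an identical config reproduces identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    writer = _Writer(outdir)
    for stage in config.stages:
        name = stage["name"]
        params = {k: v for k, v in stage.items() if k != "name"}
        logger.info("running stage %s", name)
        try:
            PRESETS[name](config.seed, writer, params)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest = dict(
        version=__version__,
        config=asdict(config),
        outputs={str(p.relative_to(outdir)): _sha256(p) for p in writer.files},
    )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
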