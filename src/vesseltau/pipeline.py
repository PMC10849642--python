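"""Run orchestration: phantom → geometry → normalize → objects → profiles → stats.

Stages communicate through files in the run directory, so any stage can
be skipped and resumed from cached outputs; a manifest records the
configuration hash, seed, and a SHA-256 per output file, making
reproducibility auditable (same config + seed ⇒ identical hashes,
timestamps aside). A single run seed fans out to per-stage substreams
via ``numpy.random.SeedSequence`` so stage order cannot silently change
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Centerline, DistanceField, VesselRecord
from .io import (
    RunConfig,
    read_anchor_table,
    read_object_table,
    read_layer_volume,
    read_volume,
    write_anchor_table,
    write_object_table,
    write_results,
    write_volume,
)
from .normalize import (
    AnchorMeasurements,
    average_anchors,
    fit_piecewise_map,
    normalize_volume,
    reference_from_cohort,
)
from .objects import assign_layers, match_colocalized, segment_objects
from .phantom import (
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    sample_anchor_measurements,
)
from .profiles import (
    bin_along_vessel,
    heatmap_table,
    layer_summaries,
    locate_objects,
    object_density,
    percent_nft_by_decile,
    radial_profile,
    rank_deciles,
)
from .stats import rm_anova
from .volumes import ImageVolume

__all__ = ["STAGES", "RunManifest", "run_pipeline", "validate_config", "demo_spec"]

log = logging.getLogger(__name__)

STAGES = ["phantom", "geometry", "normalize", "objects", "profiles", "stats"]

# tangle/neuron segmentation threshold as a fraction of the
# autofluorescence→positive anchor span, in normalized intensity space
SEGMENT_THRESHOLD_FRACTION = 0.6


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict
    timestamps: dict

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty list means the config is valid)."""
    return config.violations()


def demo_spec() -> PhantomSpec:
    """Base phantom for the demo pipeline (compact but fully featured)."""
    return PhantomSpec(shape=(48, 192, 192), voxel_size=(1.0, 1.0, 1.0))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig, seed: int, n_donors: int, n_vessels: int,
                 base_spec: PhantomSpec) -> str:
    payload = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "n_donors": n_donors,
        "n_vessels": n_vessels,
        "spec": {
            "shape": list(base_spec.shape),
            "voxel_size": list(base_spec.voxel_size),
            "levels": list(base_spec.anchor_levels),
            "noise_sd": base_spec.noise_sd,
            "neuron_density_per_mm3": base_spec.neuron_density_per_mm3,
            "nft_beta": [base_spec.nft_beta0, base_spec.nft_beta1],
        },
    }
    return hashlib.sha256(
        yaml.safe_dump(payload, sort_keys=True).encode()
    ).hexdigest()


def _donor_dirs(outdir: Path) -> list[Path]:
    return sorted((outdir / "donors").glob("donor*"))


def _stage_done(outdir: Path, stage: str) -> bool:
    return (outdir / ".stages" / stage).exists()


def _mark_done(outdir: Path, stage: str) -> None:
    d = outdir / ".stages"
    d.mkdir(parents=True, exist_ok=True)
    (d / stage).write_text("done\n")


# ---------------------------------------------------------------------------
# stage implementations (file-to-file)


def _stage_phantom(outdir: Path, base_spec: PhantomSpec, n_donors: int,
                   n_vessels: int, seed: int) -> None:
    cohort = generate_cohort(n_donors, base_spec, seed=seed, n_vessels=n_vessels)
    for donor_id, spec in cohort:
        ddir = outdir / "donors" / donor_id
        ddir.mkdir(parents=True, exist_ok=True)
        res = generate_phantom(spec)
        for name, vol in res.channels.items():
            write_volume(vol, ddir / f"{name.lower()}.h5")
        write_volume(
            ImageVolume(res.layers.labels.astype(np.float64), spec.voxel_size, "layers"),
            ddir / "layers.h5",
        )
        mdir = ddir / "masks"
        mdir.mkdir(exist_ok=True)
        for vid, mask in enumerate(res.vessel_masks):
            write_volume(
                ImageVolume(mask.astype(np.float64), spec.voxel_size, f"mask_{vid}"),
                mdir / f"vessel_{vid}.h5",
            )
        res.ground_truth.bins.to_csv(ddir / "truth_bins.csv", index=False)
        res.ground_truth.neurons.to_csv(ddir / "truth_neurons.csv", index=False)
        anchors = sample_anchor_measurements(
            res, spec, rng=np.random.default_rng((spec.seed + 1) % (2**31))
        )
        write_anchor_table(anchors.as_dict(), ddir / "anchors.csv")
        with open(ddir / "donor_meta.json", "w") as fh:
            json.dump({"donor_id": donor_id, "voxel_size": list(spec.voxel_size),
                       "n_vessels": len(spec.vessels)}, fh, sort_keys=True)


def _load_donor_meta(ddir: Path) -> dict:
    with open(ddir / "donor_meta.json") as fh:
        return json.load(fh)


def _stage_geometry(outdir: Path, config: RunConfig) -> None:
    for ddir in _donor_dirs(outdir):
        meta = _load_donor_meta(ddir)
        vs = tuple(meta["voxel_size"])
        vdir = ddir / "vessels"
        vdir.mkdir(exist_ok=True)
        rows = []
        for vid in range(meta["n_vessels"]):
            mask = read_volume(ddir / "masks" / f"vessel_{vid}.h5", voxel_size=vs).data > 0.5
            rec = VesselRecord.from_mask(
                mask, vs, vessel_id=vid, donor_id=meta["donor_id"],
                max_distance_um=config.export_radius_um,
            )
            cl = rec.centerline
            pd.DataFrame(
                {
                    "z_um": cl.nodes[:, 0], "y_um": cl.nodes[:, 1],
                    "x_um": cl.nodes[:, 2],
                    "cumulative_arclength_um": cl.cumulative_arclength,
                }
            ).to_csv(vdir / f"vessel_{vid}_centerline.csv", index=False)
            write_volume(
                ImageVolume(rec.distance_field.values, vs, f"distance_{vid}"),
                vdir / f"vessel_{vid}_distance.h5",
            )
            rows.append({"vessel_id": vid, "diameter_um": rec.diameter_um,
                         "total_length_um": rec.total_length_um})
        pd.DataFrame(rows).to_csv(vdir / "vessels_meta.csv", index=False)


def _load_vessels(ddir: Path, config: RunConfig) -> list[VesselRecord]:
    meta = _load_donor_meta(ddir)
    vs = tuple(meta["voxel_size"])
    vdir = ddir / "vessels"
    vmeta = pd.read_csv(vdir / "vessels_meta.csv")
    records = []
    for row in vmeta.itertuples(index=False):
        vid = int(row.vessel_id)
        mask = read_volume(ddir / "masks" / f"vessel_{vid}.h5", voxel_size=vs).data > 0.5
        cl_df = pd.read_csv(vdir / f"vessel_{vid}_centerline.csv")
        cl = Centerline(
            cl_df[["z_um", "y_um", "x_um"]].to_numpy(),
            cl_df["cumulative_arclength_um"].to_numpy(),
        )
        dist = read_volume(vdir / f"vessel_{vid}_distance.h5", voxel_size=vs).data
        records.append(
            VesselRecord(
                vessel_id=vid, donor_id=meta["donor_id"], mask=mask, voxel_size=vs,
                centerline=cl,
                distance_field=DistanceField(dist, vs, config.export_radius_um),
                diameter_um=float(row.diameter_um),
            )
        )
    return records


def _stage_normalize(outdir: Path) -> None:
    ddirs = _donor_dirs(outdir)
    triples = {}
    for ddir in ddirs:
        anchors = AnchorMeasurements.from_dict(read_anchor_table(ddir / "anchors.csv"))
        triples[ddir.name] = average_anchors(anchors)
    reference = reference_from_cohort(triples.values())
    maps = {}
    for ddir in ddirs:
        meta = _load_donor_meta(ddir)
        vs = tuple(meta["voxel_size"])
        pmap = fit_piecewise_map(triples[ddir.name], reference)
        maps[ddir.name] = {
            "sample_anchors": list(pmap.sample_anchors),
            "reference_anchors": list(pmap.reference_anchors),
        }
        for ch in ("at8", "hud"):
            vol = read_volume(ddir / f"{ch}.h5", channel=ch.upper(), voxel_size=vs)
            write_volume(normalize_volume(vol, pmap), ddir / f"{ch}_norm.h5")
    with open(outdir / "normalization_maps.json", "w") as fh:
        json.dump({"reference_anchors": list(reference), "maps": maps}, fh,
                  indent=2, sort_keys=True)


def _stage_objects(outdir: Path, config: RunConfig) -> None:
    with open(outdir / "normalization_maps.json") as fh:
        ref = json.load(fh)["reference_anchors"]
    threshold = ref[1] + SEGMENT_THRESHOLD_FRACTION * (ref[2] - ref[1])
    for ddir in _donor_dirs(outdir):
        meta = _load_donor_meta(ddir)
        vs = tuple(meta["voxel_size"])
        at8 = read_volume(ddir / "at8_norm.h5", channel="AT8", voxel_size=vs)
        hud = read_volume(ddir / "hud_norm.h5", channel="HuD", voxel_size=vs)
        layers = read_layer_volume(ddir / "layers.h5", voxel_size=vs)
        tangles = segment_objects(
            at8, threshold, min_size=config.min_object_size,
            max_size=config.max_object_size, object_class="tangle",
            connectivity=config.connectivity,
        )
        neurons = segment_objects(
            hud, threshold, min_size=config.min_object_size,
            max_size=config.max_object_size, object_class="neuron",
            connectivity=config.connectivity,
        )
        match_colocalized(tangles, neurons, config.overlap_fraction)
        assign_layers(tangles, layers)
        assign_layers(neurons, layers)
        log.info(
            "%s: %d tangles, %d neurons (%d NFT-positive)",
            ddir.name, len(tangles), len(neurons),
            sum(bool(r.nft_positive) for r in neurons.records),
        )
        # tangles first, then neurons, with globally unique ids per donor
        combined = []
        for rec in tangles.records + neurons.records:
            rec = dataclasses.replace(rec)
            rec.object_id = len(combined) + 1
            combined.append(rec)
        write_object_table(combined, ddir / "objects.csv")


def _stage_profiles(outdir: Path, config: RunConfig) -> pd.DataFrame:
    all_bins, all_radial, all_heat = [], [], []
    for ddir in _donor_dirs(outdir):
        meta = _load_donor_meta(ddir)
        donor = meta["donor_id"]
        vs = tuple(meta["voxel_size"])
        at8 = read_volume(ddir / "at8_norm.h5", channel="AT8", voxel_size=vs)
        layers = read_layer_volume(ddir / "layers.h5", voxel_size=vs)
        vessels = _load_vessels(ddir, config)
        objects = read_object_table(ddir / "objects.csv")
        bins = pd.concat(
            [bin_along_vessel(at8, v, config, layers, donor_id=donor) for v in vessels],
            ignore_index=True,
        )
        bins = rank_deciles(bins, config)
        objects = locate_objects(objects, vessels, config)
        bins = object_density(bins, objects, config, donor_id=donor)
        all_bins.append(bins)
        all_radial.append(radial_profile(at8, vessels, bins, config, donor_id=donor))
        all_heat.append(heatmap_table(bins, float(at8.data.mean())))
    bins = pd.concat(all_bins, ignore_index=True)
    tables = {
        "bins": bins,
        "radial_profile": pd.concat(all_radial, ignore_index=True),
        "layer_summary": layer_summaries(bins),
        "heatmap": pd.concat(all_heat, ignore_index=True),
        "nft_by_decile": percent_nft_by_decile(bins, config.n_deciles).reset_index(),
    }
    write_results(tables, outdir)
    return bins


def _stage_stats(outdir: Path, config: RunConfig) -> None:
    table = pd.read_csv(outdir / "nft_by_decile.csv").set_index("donor")
    payload: dict = {}
    try:
        res = rm_anova(table)
        payload["rm_anova"] = res.to_dict()
    except ValueError as exc:
        payload["rm_anova"] = {"error": str(exc)}
    with open(outdir / "stats.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    n_donors: int = 3,
    n_vessels: int = 2,
    through: str = "stats",
    resume: bool = False,
) -> RunManifest:
    """Run the pipeline end to end (or up to ``through``) into ``outdir``.

    Validation happens before any compute; a failing stage aborts with
    the stage named, retaining partial outputs. With ``resume=True``,
    stages whose outputs already exist under a matching configuration
    hash are skipped.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    base_spec = base_spec or demo_spec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config, seed, n_donors, n_vessels, base_spec)

    hash_file = outdir / ".config_hash"
    if resume and hash_file.exists() and hash_file.read_text().strip() != chash:
        raise ValueError("cannot resume: configuration differs from the cached run")
    hash_file.write_text(chash + "\n")

    timestamps: dict[str, float] = {}
    runners = {
        "phantom": lambda: _stage_phantom(outdir, base_spec, n_donors, n_vessels, seed),
        "geometry": lambda: _stage_geometry(outdir, config),
        "normalize": lambda: _stage_normalize(outdir),
        "objects": lambda: _stage_objects(outdir, config),
        "profiles": lambda: _stage_profiles(outdir, config),
        "stats": lambda: _stage_stats(outdir, config),
    }
    for stage in STAGES[: STAGES.index(through) + 1]:
        if resume and _stage_done(outdir, stage):
            log.info("stage %s: cached, skipping", stage)
            continue
        t0 = time.time()
        try:
            runners[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _mark_done(outdir, stage)
        timestamps[stage] = time.time() - t0
        log.info("stage %s: %.1f s", stage, timestamps[stage])

    stage_outputs: dict[str, dict] = {}
    tracked = [
        p for p in outdir.rglob("*")
        if p.is_file() and p.suffix in {".csv", ".h5", ".json"}
        and p.name != "manifest.json"
    ]
    stage_outputs["files"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(tracked)
    }
    manifest = RunManifest(
        config_hash=chash,
        seed=seed,
        version=__version__,
        stages=stage_outputs,
        timestamps={k: round(v, 3) for k, v in timestamps.items()},
    )
    manifest.save(outdir / "manifest.json")
    return manifest
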