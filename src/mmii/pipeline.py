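"""Whole-case orchestration: register everything to the base T1, compute
SISCOM, build the Talairach frame, check trajectories, localize contacts
and evaluate the resection proposal — from one case configuration file.

The pipeline only composes the module operations in a fixed stage order
(registration -> SISCOM -> grid -> trajectories -> contacts -> resection);
it adds no computation of its own and never takes clinical decisions.
Absent modalities are skipped with a log line; a failing stage is recorded
and independent stages still run.  Every artifact written is listed in a
manifest with its stage, inputs, parameters and SHA-256 checksum, so a
rerun with the same configuration and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contacts as contacts_mod
from . import resection as resection_mod
from . import siscom as siscom_mod
from . import talairach as tal_mod
from . import trajectory as traj_mod
from .errors import MMIIError, ValidationError
from .registration import (RegistrationOptions, register_rigid, resample)
from .volumes_io import (BurnSettings, ImageVolume, PointSet, RigidTransform,
                         burn_lines, read_pointset, read_volume,
                         write_pointset, write_volume)

logger = logging.getLogger("mmii")

#: Modalities the registration stage looks for in the configuration.
REGISTERABLE = ("t2", "flair", "pet", "spect_ictal", "spect_interictal",
                "ct", "cta", "postop_mri")


@dataclass
class CaseConfig:
    """One case: file paths, landmarks and processing parameters.

    Only ``t1`` is required.  Modalities whose path is ``None`` are
    skipped.  ``aligned`` lists modalities already in the base frame (their
    registration is skipped and the identity transform recorded).
    """

    t1: str
    out_dir: str = "mmii_out"
    t2: str | None = None
    flair: str | None = None
    pet: str | None = None
    spect_ictal: str | None = None
    spect_interictal: str | None = None
    ct: str | None = None
    cta: str | None = None
    postop_mri: str | None = None
    brain_mask: str | None = None
    vessel_mask: str | None = None
    plan: str | None = None
    markers: str | None = None
    meg_dipoles: str | None = None
    aligned: list[str] = field(default_factory=list)
    ac: list[float] | None = None
    pc: list[float] | None = None
    ms: list[float] | None = None
    bounds: dict | None = None
    siscom_z: float = 1.5
    siscom_min_voxels: int = 5
    siscom_smooth_fwhm: float = 0.0
    clearance: float = 3.0
    coverage_radius: float = 5.0
    contact_threshold: float | None = None
    contact_tol: float = 4.0
    brush_radius: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t1:
            raise ValidationError("case config requires a base T1 path")
        if self.siscom_z <= 0 or self.clearance <= 0:
            raise ValidationError("thresholds must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CaseConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CaseBundle:
    """Everything :func:`run_case` produced, in memory plus on disk."""

    base: ImageVolume
    registered: dict = field(default_factory=dict)     # name -> ImageVolume
    transforms: dict = field(default_factory=dict)     # name -> RigidTransform
    zmap: object | None = None
    clusters: list = field(default_factory=list)
    frame: object | None = None
    safety: object | None = None
    coverage: object | None = None
    contact_set: object | None = None
    containment: object | None = None
    resection_mask: object | None = None
    manifest: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)         # stage -> message


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: dict = {}

    def record(self, path: Path, stage: str, inputs: list[str],
               params: dict) -> None:
        self.entries[path.name] = {
            "stage": stage, "inputs": inputs,
            "params": {k: (v if isinstance(v, (int, float, str, bool,
                                               type(None))) else str(v))
                       for k, v in params.items()},
            "sha256": _sha256(path)}

    def write(self) -> Path:
        p = self.out_dir / "manifest.json"
        p.write_text(json.dumps(self.entries, indent=1, sort_keys=True))
        return p


def run_case(cfg: CaseConfig) -> CaseBundle:
    """Run the full integration workflow for one case.

    Deterministic for a fixed configuration and seed.  A missing base T1 is
    fatal; any other stage failure is recorded in ``bundle.errors`` and the
    remaining independent stages still run.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    manifest = _Manifest(out_dir)
    events: list[dict] = []

    def event(stage: str, msg: str) -> None:
        logger.info("[%s] %s", stage, msg)
        events.append({"stage": stage, "message": msg})

    base = read_volume(cfg.t1, modality="t1")
    base.frame_id = "base"
    bundle = CaseBundle(base=base)

    def run_stage(name, fn):
        try:
            fn()
        except Exception as exc:  # record and continue with later stages
            bundle.errors[name] = f"{type(exc).__name__}: {exc}"
            logger.error("[%s] stage failed: %s\n%s", name, exc,
                         traceback.format_exc())
            events.append({"stage": name, "error": str(exc)})

    # ---- registration ----------------------------------------------------
    def do_registration():
        opts = RegistrationOptions(seed=cfg.seed)
        for name in REGISTERABLE:
            path = getattr(cfg, name)
            if path is None:
                event("register", f"{name}: absent, skipped")
                continue
            vol = read_volume(path)
            if name in cfg.aligned:
                t = RigidTransform.identity()
                event("register", f"{name}: declared aligned, identity "
                                  "transform recorded")
            else:
                o = opts if name != "postop_mri" else RegistrationOptions(
                    seed=cfg.seed, mask_zero_fixed=True)
                res = register_rigid(vol, base, o)
                t = res.transform
                event("register",
                      f"{name}: MI {res.metric_before:.3f} -> "
                      f"{res.metric_after:.3f} bits, "
                      f"converged={res.converged}")
            reg = resample(vol, t, base)
            reg.modality = vol.modality
            vpath = out_dir / f"{name}_base.nii.gz"
            tpath = out_dir / f"{name}_transform.json"
            write_volume(reg, vpath)
            t.save(tpath)
            manifest.record(vpath, "register", [path], {"seed": cfg.seed})
            manifest.record(tpath, "register", [path], {"seed": cfg.seed})
            bundle.registered[name] = reg
            bundle.transforms[name] = t

    run_stage("register", do_registration)

    # ---- SISCOM ----------------------------------------------------------
    def do_siscom():
        ictal = bundle.registered.get("spect_ictal")
        inter = bundle.registered.get("spect_interictal")
        if ictal is None or inter is None:
            event("siscom", "perfusion pair incomplete, skipped")
            return
        if cfg.brain_mask:
            mask = read_volume(cfg.brain_mask, modality="mask")
        else:
            mask = siscom_mod.default_brain_mask(base)
            event("siscom", "no brain mask supplied; Otsu mask from T1")
        zm = siscom_mod.compute_siscom(ictal, inter, mask,
                                       smooth_fwhm=cfg.siscom_smooth_fwhm)
        zm.threshold = cfg.siscom_z
        bundle.zmap = zm
        bundle.clusters = siscom_mod.threshold_clusters(
            zm, cfg.siscom_z, cfg.siscom_min_voxels)
        zpath = out_dir / "siscom_z.nii.gz"
        write_volume(zm.as_volume(), zpath)
        cpath = out_dir / "siscom_clusters.tsv"
        siscom_mod.clusters_to_table(bundle.clusters).to_csv(
            cpath, sep="\t", index=False)
        manifest.record(zpath, "siscom",
                        [cfg.spect_ictal, cfg.spect_interictal],
                        {"z": cfg.siscom_z,
                         "smooth_fwhm": cfg.siscom_smooth_fwhm})
        manifest.record(cpath, "siscom", [], {"z": cfg.siscom_z,
                                              "min_voxels":
                                              cfg.siscom_min_voxels})
        event("siscom", f"{len(bundle.clusters)} clusters at z >= "
                        f"{cfg.siscom_z}")

    run_stage("siscom", do_siscom)

    # ---- Talairach grid --------------------------------------------------
    def do_grid():
        if cfg.ac is None or cfg.pc is None or cfg.ms is None \
                or cfg.bounds is None:
            event("talairach", "landmarks/bounds absent, skipped")
            return
        frame = tal_mod.build_frame(cfg.ac, cfg.pc, cfg.ms,
                                    tal_mod.BrainBounds(**cfg.bounds))
        bundle.frame = frame
        fpath = out_dir / "talairach_frame.json"
        frame.save(fpath)
        manifest.record(fpath, "talairach", [], {"ac": cfg.ac,
                                                 "pc": cfg.pc})
        event("talairach", "frame built")

    run_stage("talairach", do_grid)

    # ---- trajectories ----------------------------------------------------
    def do_trajectories():
        if cfg.plan is None:
            event("plan", "no trajectory plan, skipped")
            return
        plan = traj_mod.load_plan(cfg.plan)
        trajectories = [e.trajectory for e in plan]
        vessels = None
        if cfg.vessel_mask:
            vessels = read_volume(cfg.vessel_mask, modality="cta")
        elif "cta" in bundle.registered:
            vessels = bundle.registered["cta"]
        if vessels is not None:
            reports = [traj_mod.vessel_clearance(t, vessels, cfg.clearance)
                       for t in trajectories]
            bundle.safety = traj_mod.safety_table(reports)
            spath = out_dir / "trajectory_safety.tsv"
            bundle.safety.to_csv(spath, sep="\t", index=False)
            manifest.record(spath, "plan", [cfg.plan],
                            {"clearance": cfg.clearance})
            event("plan", f"clearance checked for {len(reports)} "
                          "trajectories")
        else:
            event("plan", "no vessel mask, clearance skipped")
        if cfg.meg_dipoles:
            targets = read_pointset(cfg.meg_dipoles)
            bundle.coverage = traj_mod.target_coverage(
                trajectories, targets, cfg.coverage_radius)
            cpath = out_dir / "target_coverage.tsv"
            bundle.coverage.to_csv(cpath, sep="\t", index=False)
            manifest.record(cpath, "plan", [cfg.meg_dipoles],
                            {"radius": cfg.coverage_radius})
        lpath = out_dir / "trajectories_burned.nii.gz"
        write_volume(burn_lines(base, trajectories, BurnSettings()), lpath)
        manifest.record(lpath, "plan", [cfg.plan, cfg.t1], {})

    run_stage("plan", do_trajectories)

    # ---- contacts --------------------------------------------------------
    def do_contacts():
        ct = bundle.registered.get("ct")
        if ct is None or cfg.plan is None:
            event("contacts", "post-implant CT or plan absent, skipped")
            return
        plan = traj_mod.load_plan(cfg.plan)
        # candidates are segmented on the native CT grid (full resolution),
        # in base-frame world coordinates via the stored transform
        native_ct = read_volume(cfg.ct)
        t = bundle.transforms["ct"]
        cand = contacts_mod.segment_contact_candidates(
            native_ct, threshold=cfg.contact_threshold)
        moved = PointSet([p._replace(**dict(zip(
            ("x", "y", "z"), map(float, t.apply(p.xyz)[0]))))
            for p in cand])
        cs = contacts_mod.assign_and_name(
            moved, [e.trajectory for e in plan], tol=cfg.contact_tol)
        bundle.contact_set = cs
        cpath = out_dir / "contacts.tsv"
        cs.to_dataframe().to_csv(cpath, sep="\t", index=False)
        ppath = out_dir / "contacts.json"
        write_pointset(cs.as_pointset(), ppath)
        manifest.record(cpath, "contacts", [cfg.ct, cfg.plan],
                        {"tol": cfg.contact_tol,
                         "threshold": cfg.contact_threshold})
        manifest.record(ppath, "contacts", [cfg.ct, cfg.plan], {})
        event("contacts", f"{len(cs.contacts)} contacts named, "
                          f"{len(cs.unassigned)} unassigned")

    run_stage("contacts", do_contacts)

    # ---- resection -------------------------------------------------------
    def do_resection():
        if cfg.markers is None:
            event("resect", "no pass markers, skipped")
            return
        markers = read_pointset(cfg.markers)
        rm = resection_mod.markers_to_mask(markers, cfg.brush_radius, base)
        bundle.resection_mask = rm
        mpath = out_dir / "resection_mask.nii.gz"
        write_volume(rm.as_volume(), mpath)
        verts, faces = resection_mod.mask_to_voxel_mesh(rm)
        opath = out_dir / "resection_mesh.obj"
        resection_mod.write_obj(verts, faces, opath)
        bpath = out_dir / "resection_burned.nii.gz"
        write_volume(resection_mod.export_burned_mask(base, rm), bpath)
        for p in (mpath, opath, bpath):
            manifest.record(p, "resect", [cfg.markers, cfg.t1],
                            {"brush_radius": cfg.brush_radius})
        if bundle.contact_set is not None:
            bundle.containment = resection_mod.mask_contains(
                rm, bundle.contact_set.as_pointset())
            tpath = out_dir / "resection_containment.tsv"
            bundle.containment.to_csv(tpath, sep="\t", index=False)
            manifest.record(tpath, "resect", [cfg.markers], {})
        event("resect", f"mask of {rm.voxel_count} voxels")

    run_stage("resect", do_resection)

    bundle.manifest = manifest.entries
    manifest.write()
    (out_dir / "events.json").write_text(json.dumps(events, indent=1))
    return bundle


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")).parent == out_dir
               for h in logger.handlers):
        fh = logging.FileHandler(out_dir / "mmii.log")
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
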