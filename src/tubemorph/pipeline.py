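"""Study-level orchestration: masks or meshes in, contrasts and reports out.

The statsmodels-style entry point is :class:`MorphometryStudy` — built from
a cohort of surfaces plus a :class:`PipelineConfig`, its :meth:`fit` runs
correspondence, feature extraction and the permutation contrasts, returning
a :class:`StudyResults` carrying per-contrast significance, ratio maps,
p-value CDF diagnostics, volumes and the demographics table, with
``summary()`` and ``save()``.

Per-subject geometry is cached by content hash, so re-running an unchanged
configuration recomputes nothing and reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .cohort import demographics_table
from .correspondence import (DEFAULT_GRID, GridSurface, RegistrationParams,
                             compute_cuts, conformal_parameterize,
                             fluid_register, resample_to_grid)
from .errors import ParameterError
from .mesh import mesh_volume
from .morphometry import MMSFeatureMatrix, compute_mms
from .stats import (DEFAULT_ALPHA, DEFAULT_N_PERM,
                    HotellingPermutationTest, compare_volumes,
                    pvalue_cdf, ratio_map)
from .synthetic import SyntheticCohort, make_demographics

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (("carriers", "NC"), ("HT", "NC"), ("HM", "NC"),
                     ("HT", "HM"))


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults mirror the study's printed settings
    (W = 100 x 150 = 15,000 analysis vertices per side, 10,000
    permutations, alpha = 0.05)."""

    output_dir: str = "tubemorph_out"
    n_u: int = DEFAULT_GRID[0]
    n_v: int = DEFAULT_GRID[1]
    cap_fraction: float = 0.02
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    radial_frame: str = "subject"
    contrasts: tuple = DEFAULT_CONTRASTS
    cache: bool = True

    @property
    def n_vertices(self) -> int:
        return self.n_u * self.n_v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        reg = RegistrationParams(**raw.pop("registration", {}))
        cfg = cls(registration=reg, **raw)
        if "contrasts" in raw:
            cfg.contrasts = tuple(tuple(c) for c in raw["contrasts"])
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    features: MMSFeatureMatrix
    volume: float
    qc: dict


@dataclass
class StudyResults:
    """Fitted study: estimates, uncertainties and diagnostics."""

    contrasts: dict                      # name -> ContrastResult
    ratio_maps: dict                     # name -> RatioMap
    cdf: dict                            # name -> (sorted_p, ecdf, deviation)
    volumes: pd.DataFrame                # subject_id, group, volume_mm3
    volume_pvalues: dict                 # name -> permutation p
    subjects: list                       # SubjectRecord in processing order
    demographics: pd.DataFrame | None
    demographics_summary: pd.DataFrame | None
    template_grid: GridSurface
    config: PipelineConfig
    runtime_s: float = 0.0

    def volume_table(self) -> pd.DataFrame:
        g = self.volumes.groupby("group")["volume_mm3"]
        return pd.DataFrame({"mean": g.mean().round(2),
                             "sd": g.std(ddof=1).round(2),
                             "n": g.count()})

    def summary(self) -> str:
        lines = ["Surface morphometry study", "=" * 60,
                 f"subjects: {len(self.subjects)}   analysis vertices: "
                 f"{self.config.n_vertices}   permutations: {self.config.n_perm}",
                 "", "Volumes (mm^3):", self.volume_table().to_string(), "",
                 "Contrasts (vertex-wise multivariate morphometry):"]
        for name, c in self.contrasts.items():
            dev = self.cdf[name][2]
            vol_p = self.volume_pvalues.get(name)
            lines.append(
                f"  {name:16s} p_feature {c.p_feature:6d}  corrected p "
                f"{c.corrected_p:7.4f}{' *' if c.significant else '  '} "
                f"CDF deviation {dev:5.3f}  volume p {vol_p:.3f}")
        if self.demographics_summary is not None:
            lines += ["", "Demographics:",
                      self.demographics_summary.to_string()]
        return "\n".join(lines)

    def save(self, outdir=None) -> Path:
        from .io import save_grid_surface, write_vtk_structured_grid

        out = Path(outdir or self.config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_grid_surface(out / "template_grid", self.template_grid)
        self.volumes.to_csv(out / "volumes.csv", index=False)
        self.volume_table().to_csv(out / "volume_table.csv")
        if self.demographics is not None:
            self.demographics.to_csv(out / "demographics.csv", index=False)
        if self.demographics_summary is not None:
            self.demographics_summary.to_csv(out / "demographics_table.csv")
        contrast_summary = {}
        for name, c in self.contrasts.items():
            rm = self.ratio_maps[name]
            write_vtk_structured_grid(
                out / f"contrast_{name}.vtk", self.template_grid,
                point_data={"statistic_M": c.statistic,
                            "p_uncorrected": c.p_uncorrected,
                            "significant": c.mask.astype(float),
                            "ratio_R": np.nan_to_num(rm.ratio, nan=-1.0)})
            sp, ecdf, dev = self.cdf[name]
            pd.DataFrame({"p_sorted": sp, "ecdf": ecdf}).to_csv(
                out / f"cdf_{name}.csv", index=False)
            contrast_summary[name] = dict(
                c.to_dict(), cdf_deviation=float(dev),
                volume_p=float(self.volume_pvalues[name]),
                n_atrophy_vertices=int(rm.atrophy_mask.sum()),
                n_expansion_vertices=int(rm.expansion_mask.sum()))
        (out / "contrasts.json").write_text(json.dumps(contrast_summary,
                                                       indent=2))
        manifest = {
            "tubemorph_version": __version__,
            "config": json.loads(json.dumps(dataclasses.asdict(self.config),
                                            default=str)),
            "n_subjects": len(self.subjects),
            "subject_qc": {s.subject_id: s.qc for s in self.subjects},
            "runtime_s": round(self.runtime_s, 2),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        return out


def _process_mesh(mesh: trimesh.Trimesh, config: PipelineConfig):
    """Closed mesh -> grid surface, with QC metrics."""
    om = compute_cuts(mesh, config.cap_fraction)
    ps = conformal_parameterize(om)
    grid = resample_to_grid(ps, config.n_u, config.n_v)
    qc = {"fallback_nodes": int(grid.fallback_nodes)}
    return grid, qc


def _content_hash(mesh: trimesh.Trimesh, config: PipelineConfig) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    key = (config.n_u, config.n_v, config.cap_fraction, config.radial_frame,
           tuple(sorted(dataclasses.asdict(config.registration).items())))
    h.update(repr(key).encode())
    return h.hexdigest()[:16]


class MorphometryStudy:
    """Model object: a cohort of closed surfaces with group labels and a
    designated template, ready to ``fit()``.

    Left and right structures are separate studies — build one instance per
    side and never mix sides in a contrast.
    """

    def __init__(self, meshes: list, labels: list,
                 template: trimesh.Trimesh,
                 config: PipelineConfig | None = None,
                 demographics: pd.DataFrame | None = None,
                 truth_mask_lookup=None):
        if len(meshes) != len(labels):
            raise ParameterError("one label per mesh required")
        counts = pd.Series(list(labels)).value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ParameterError("need >= 2 groups with >= 2 subjects each")
        self.meshes = list(meshes)
        self.labels = list(labels)
        self.template = template
        self.config = config or PipelineConfig()
        self.demographics = demographics
        self.truth_mask_lookup = truth_mask_lookup

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort,
                    config: PipelineConfig | None = None,
                    demographics: pd.DataFrame | None = None
                    ) -> "MorphometryStudy":
        if demographics is None:
            demographics = make_demographics(cohort.spec.group_sizes,
                                             seed=cohort.spec.seed)
        return cls(cohort.meshes, cohort.labels, cohort.template,
                   config=config, demographics=demographics,
                   truth_mask_lookup=cohort.truth_mask_at)

    @classmethod
    def from_manifest(cls, manifest_csv,
                      config: PipelineConfig | None = None,
                      template_path=None) -> "MorphometryStudy":
        """Manifest CSV columns: subject_id, group, mesh_path."""
        from .io import read_mesh

        df = pd.read_csv(manifest_csv)
        meshes = []
        for _, row in df.iterrows():
            m = read_mesh(row["mesh_path"])
            m.metadata["subject_id"] = row["subject_id"]
            m.metadata["group"] = row["group"]
            meshes.append(m)
        template = read_mesh(template_path) if template_path else meshes[0]
        return cls(meshes, df["group"].tolist(), template, config=config)

    # -- fitting ------------------------------------------------------------

    def _subject_features(self, mesh, template_grid, cache_dir):
        cfg = self.config
        key = None
        if cache_dir is not None:
            key = _content_hash(mesh, cfg)
            path = cache_dir / f"{key}.npz"
            if path.exists():
                z = np.load(path, allow_pickle=False)
                feats = MMSFeatureMatrix(
                    mms=z["mms"], det_j=z["det_j"],
                    grid_shape=tuple(z["grid_shape"]),
                    subject_id=mesh.metadata.get("subject_id"),
                    det_j_param=z["det_j_param"])
                return feats, {"cache": "hit"}
        grid, qc = _process_mesh(mesh, cfg)
        fld = fluid_register(grid, template_grid, cfg.registration)
        qc["ic_p95_cells"] = round(float(fld.ic_p95), 4)
        qc["registration_iterations"] = len(fld.convergence["backward_ssd"])
        feats = compute_mms(grid, template_grid, fld,
                            radial_frame=cfg.radial_frame)
        if cache_dir is not None:
            np.savez(cache_dir / f"{key}.npz", mms=feats.mms,
                     det_j=feats.det_j, det_j_param=feats.det_j_param,
                     grid_shape=np.array(feats.grid_shape))
        return feats, qc

    def fit(self) -> StudyResults:
        cfg = self.config
        t_start = time.time()
        cache_dir = None
        if cfg.cache:
            cache_dir = Path(cfg.output_dir) / "cache"
            cache_dir.mkdir(parents=True, exist_ok=True)

        template_grid, _ = _process_mesh(self.template, cfg)
        subjects = []
        group_feats: dict[str, list] = {}
        group_detj: dict[str, list] = {}
        group_vols: dict[str, list] = {}
        for mesh, group in zip(self.meshes, self.labels):
            sid = mesh.metadata.get("subject_id", f"subj_{len(subjects):03d}")
            t0 = time.time()
            feats, qc = self._subject_features(mesh, template_grid, cache_dir)
            vol = mesh_volume(mesh)
            qc["elapsed_s"] = round(time.time() - t0, 3)
            log.info("subject %s (%s): %.3fs %s", sid, group,
                     qc["elapsed_s"], qc)
            subjects.append(SubjectRecord(sid, group, feats, vol, qc))
            group_feats.setdefault(group, []).append(feats.mms)
            group_detj.setdefault(group, []).append(feats.det_j)
            group_vols.setdefault(group, []).append(vol)

        def members(tag):
            if tag == "carriers":
                return group_feats.get("HT", []) + group_feats.get("HM", [])
            return group_feats.get(tag, [])

        def members_detj(tag):
            if tag == "carriers":
                return group_detj.get("HT", []) + group_detj.get("HM", [])
            return group_detj.get(tag, [])

        def members_vols(tag):
            if tag == "carriers":
                return group_vols.get("HT", []) + group_vols.get("HM", [])
            return group_vols.get(tag, [])

        contrasts, ratios, cdfs, vol_ps = {}, {}, {}, {}
        for i, (g2, g1) in enumerate(cfg.contrasts):
            a, b = members(g1), members(g2)         # g1 = reference group
            if len(a) < 2 or len(b) < 2:
                log.warning("skipping contrast %s vs %s (missing group)",
                            g2, g1)
                continue
            name = f"{g2}_vs_{g1}"
            seed_i = cfg.seed + 101 * (i + 1)
            test = HotellingPermutationTest(np.stack(a), np.stack(b),
                                            alpha=cfg.alpha)
            res = test.fit(n_perm=cfg.n_perm, seed=seed_i)
            contrasts[name] = res
            ratios[name] = ratio_map(np.stack(members_detj(g1)),
                                     np.stack(members_detj(g2)),
                                     res.mask, (g1, g2))
            cdfs[name] = pvalue_cdf(res.p_uncorrected)
            vol_ps[name] = compare_volumes(members_vols(g1),
                                           members_vols(g2),
                                           n_perm=min(cfg.n_perm, 10_000),
                                           seed=seed_i + 1)

        volumes = pd.DataFrame({
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "volume_mm3": [s.volume for s in subjects]})
        demo_summary = None
        if self.demographics is not None:
            demo_summary = demographics_table(self.demographics)

        return StudyResults(contrasts=contrasts, ratio_maps=ratios,
                            cdf=cdfs, volumes=volumes,
                            volume_pvalues=vol_ps, subjects=subjects,
                            demographics=self.demographics,
                            demographics_summary=demo_summary,
                            template_grid=template_grid, config=cfg,
                            runtime_s=time.time() - t_start)


def run_pipeline(config: PipelineConfig,
                 cohort: SyntheticCohort | None = None,
                 manifest_csv=None, template_path=None) -> StudyResults:
    """End-to-end driver: synthetic cohort or a mesh manifest in, a saved
    results bundle out."""
    if cohort is not None:
        study = MorphometryStudy.from_cohort(cohort, config)
    elif manifest_csv is not None:
        study = MorphometryStudy.from_manifest(manifest_csv, config,
                                               template_path)
    else:
        raise ParameterError("provide a cohort or a manifest")
    results = study.fit()
    results.save()
    return results
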