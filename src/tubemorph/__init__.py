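"""tubemorph: surface-based subcortical morphometry.

From binary structure masks (or meshes) to registered grid surfaces,
multivariate tensor-based morphometry statistics, permutation-corrected
group contrasts and directionality maps — with a synthetic tube-cohort
generator so the whole pipeline is testable without imaging data.
"""

from . import errors
from .mesh import (BinaryVolume, TopologyReport, check_topology, mesh_volume,
                   reconstruct_surface, simplify_and_refine)
from .synthetic import (CohortSpec, SyntheticCohort, make_cohort,
                        make_demographics, make_template_tube, rasterize_mesh)

__version__ = "0.1.0"


def __getattr__(name):
    # heavier submodules resolved lazily so `import tubemorph` stays light
    lazy = {
        "MorphometryStudy": "pipeline", "PipelineConfig": "pipeline",
        "StudyResults": "pipeline", "run_pipeline": "pipeline",
        "HotellingPermutationTest": "stats", "permutation_pmap": "stats",
        "mahalanobis_stat": "stats", "ratio_map": "stats",
        "pvalue_cdf": "stats", "compare_volumes": "stats",
        "compute_cuts": "correspondence",
        "conformal_parameterize": "correspondence",
        "resample_to_grid": "correspondence",
        "fluid_register": "correspondence",
        "compute_mms": "morphometry", "face_jacobian": "morphometry",
        "tbm": "morphometry", "mtbm": "morphometry",
        "anova_from_summary": "cohort", "anova_from_raw": "cohort",
        "chi_square_independence": "cohort",
    }
    if name in lazy:
        import importlib

        mod = importlib.import_module(f".{lazy[name]}", __name__)
        return getattr(mod, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")


__all__ = [
    "errors",
    "BinaryVolume", "TopologyReport", "check_topology", "mesh_volume",
    "reconstruct_surface", "simplify_and_refine",
    "CohortSpec", "SyntheticCohort", "make_cohort", "make_demographics",
    "make_template_tube", "rasterize_mesh",
    "MorphometryStudy", "PipelineConfig", "StudyResults", "run_pipeline",
    "HotellingPermutationTest", "permutation_pmap", "mahalanobis_stat",
    "ratio_map", "pvalue_cdf", "compare_volumes",
    "compute_cuts", "conformal_parameterize", "resample_to_grid",
    "fluid_register", "compute_mms", "face_jacobian", "tbm", "mtbm",
    "anova_from_summary", "anova_from_raw", "chi_square_independence",
    "__version__",
]
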