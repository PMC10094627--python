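"""aromakey: non-targeted GC-MS volatile flavor compound profiling.

Internal-standard semi-quantification of identified peak tables, chemical
class composition, supervised PLS-DA with VIP-based marker selection and
permutation validation, and odor-activity-value screening of the key active
differential odorants - with a calibrated synthetic generator emulating the
Guangdong black-tea study design.
"""

from .datamodel import (
    CHEM_CLASSES,
    DEFAULT_GROUPS,
    CompoundCatalog,
    CompoundRecord,
    InjectionRecord,
    PeakTable,
    RunConfig,
    SchemaError,
    ValidationError,
)
from .io import (
    load_config,
    load_table1_oav,
    read_catalog,
    read_matrix,
    read_peak_table,
    write_matrix,
    write_peak_table,
)
from .multivariate import (
    compute_vip,
    cross_validated_q2,
    fit_plsda,
    hotelling_ellipse,
    one_hot,
    permutation_test,
)
from .pipeline import PipelineResult, run_pipeline
from .quantify import class_proportions, group_mean_concentrations, semi_quantify
from .reporting import build_heatmap_data, hierarchical_cluster, summarize_run, zscore_clip
from .screening import (
    anova_by_group,
    build_screening_report,
    compute_oav,
    screen_key_active,
    top_group_flags,
)
from .synthetic import GeneratorConfig, default_catalog, default_marker_profile, default_threshold_table, generate

__version__ = "0.1.0"
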