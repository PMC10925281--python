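"""Pipeline configuration: parameter blocks, defaults, and YAML loading.

Defaults follow the published analysis where it states a value (QC count
window 5,500-250,000 and 200-9,000 features; 14 embedding dimensions;
community-detection resolution 0.5; log2 fold-change threshold 0.25 with
Bonferroni-corrected alpha 0.05) and standard single-cell practice where it
does not (normalization target, variable-gene count, neighbourhood size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from .containers import ValidationError

#: canonical testis marker panel: cell-type label -> marker genes
DEFAULT_PANELS = {
    "GSC&SG": ("vas", "nos", "ovo"),
    "Cyst": ("dlg1", "CadN", "tj", "zfh1"),
    "spermatocyte": ("fzo", "CycB"),
    "spermatid": ("CG32106", "m-cup"),
}


@dataclass
class QCParams:
    """Per-cell quality-control windows (inclusive bounds)."""

    min_counts: int = 5500
    max_counts: int = 250000
    min_features: int = 200
    max_features: int = 9000

    def validate(self):
        if not self.min_counts < self.max_counts:
            raise ValidationError("QC: min_counts must be < max_counts")
        if not self.min_features < self.max_features:
            raise ValidationError("QC: min_features must be < max_features")


@dataclass
class AnalysisParams:
    """Embedding / clustering parameters."""

    n_components: int = 14
    resolution: float = 0.5
    n_variable_genes: int = 2000
    n_neighbors: int = 20
    normalization_target: float = None  # type: ignore[assignment]  # None = median library size

    def validate(self):
        if self.n_components < 2:
            raise ValidationError("analysis: n_components must be >= 2")
        if self.resolution <= 0:
            raise ValidationError("analysis: resolution must be > 0")
        if self.n_neighbors < 1:
            raise ValidationError("analysis: n_neighbors must be >= 1")
        if self.normalization_target is not None and self.normalization_target <= 0:
            raise ValidationError("analysis: normalization_target must be > 0")


@dataclass
class MarkerPanel:
    """Cell-type marker panels and positivity rules.

    A cell is "positive" for a marker when its raw count is at least
    ``positivity_threshold``; a cluster "predominantly" matches a panel when
    the panel score (marker positive fractions averaged) reaches
    ``predominance_fraction``.
    """

    panels: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PANELS.items()})
    positivity_threshold: int = 1
    predominance_fraction: float = 0.5
    # expression-based GSC selection: positive for all of, zero for all of
    gsc_positive: tuple = ("vas", "nos", "ovo")
    gsc_negative: tuple = ("tj", "zfh1")
    # subcluster calls: GSC = nos/ovo-rich, SG = vas-positive but nos/ovo-depleted
    gsc_concentration_min: float = 0.5
    sg_depletion_max: float = 0.5

    def validate(self):
        if not self.panels:
            raise ValidationError("markers: panels must be nonempty")
        for label, genes in self.panels.items():
            if not genes:
                raise ValidationError(f"markers: panel {label!r} is empty")
        if not 0 < self.predominance_fraction <= 1:
            raise ValidationError("markers: predominance_fraction must be in (0, 1]")
        if self.positivity_threshold < 1:
            raise ValidationError("markers: positivity_threshold must be >= 1")


@dataclass
class DEThresholds:
    """Significance thresholds for differential expression."""

    log2fc_min: float = 0.25
    alpha: float = 0.05
    pseudocount: float = 1.0
    exact_cutoff: int = 10

    def validate(self):
        if self.log2fc_min <= 0:
            raise ValidationError("de: log2fc_min must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("de: alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValidationError("de: pseudocount must be > 0")


@dataclass
class PipelineConfig:
    qc: QCParams = field(default_factory=QCParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    markers: MarkerPanel = field(default_factory=MarkerPanel)
    de: DEThresholds = field(default_factory=DEThresholds)
    seed: int = 0

    def validate(self):
        self.qc.validate()
        self.analysis.validate()
        self.markers.validate()
        self.de.validate()
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {"qc": QCParams, "analysis": AnalysisParams, "markers": MarkerPanel, "de": DEThresholds}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown key in [{section}]: {sorted(unknown)[0]!r}")
    kwargs = dict(data)
    if cls is MarkerPanel:
        for key in ("panels",):
            if key in kwargs:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        for key in ("gsc_positive", "gsc_negative"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a nested mapping.

    Unspecified keys take the documented defaults; unknown keys raise a
    :class:`ValidationError` naming the offending key.
    """
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValidationError(f"unknown config key: {sorted(unknown)[0]!r}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        block = data.get(section, {}) or {}
        if not isinstance(block, dict):
            raise ValidationError(f"config section [{section}] must be a mapping")
        kwargs[section] = _build_section(cls, block, section)
    cfg = PipelineConfig(seed=int(data.get("seed", 0)), **kwargs)
    return cfg.validate()


def load_config(path) -> PipelineConfig:
    """Load a YAML config file; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
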