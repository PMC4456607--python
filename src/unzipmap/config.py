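"""Run configuration: one YAML file drives simulation and analysis.

Sections mirror the model objects (template, signature, instrument,
remodeler) plus the analysis thresholds.  A config round-trips through
serialization unchanged, and every stochastic operation consumes the run
seed, so (config, seed) fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .models import InstrumentModel, RemodelerModel, SignatureModel
from .templates import FROM_TF_SIDE, TemplateLayout, build_template


@dataclass(frozen=True)
class TemplateSpec:
    length_bp: int = 800
    separation_bp: int = 10
    direction: str = FROM_TF_SIDE
    end_positioned: bool = False
    tf_footprint: int = 10
    with_tf: bool = True
    template_seed: int = 20150605

    def build(self) -> TemplateLayout:
        return build_template(self.length_bp, self.separation_bp, self.direction,
                              self.end_positioned, self.tf_footprint,
                              self.with_tf, self.template_seed)


@dataclass(frozen=True)
class AnalysisParams:
    """Detection and calling thresholds."""
    k_sd: float = 3.0
    min_prominence_pN: float = 1.0
    gap_bp: float = 15.0
    nuc_force_floor_pN: float = 22.0
    tf_window_bp: float = 30.0
    centroid_mode: str = "peak"
    hist_bin_bp: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_molecules: int = 20
    duration: str = "short"
    tf_bound_fraction: float = 1.0
    distort: bool = True
    render_time: bool = True
    template: TemplateSpec = field(default_factory=TemplateSpec)
    signature: SignatureModel = field(default_factory=SignatureModel)
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    remodeler: RemodelerModel = field(default_factory=RemodelerModel)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)


_SECTIONS = {
    "template": TemplateSpec,
    "signature": SignatureModel,
    "instrument": InstrumentModel,
    "remodeler": RemodelerModel,
    "analysis": AnalysisParams,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(data: dict) -> RunConfig:
    kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in data:
            continue
        if f.name in _SECTIONS:
            kwargs[f.name] = _from_dict(_SECTIONS[f.name], data[f.name])
        else:
            kwargs[f.name] = data[f.name]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: Union[str, Path]) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def _preset(name, **kw) -> RunConfig:
    template = kw.pop("template")
    remodeler = kw.pop("remodeler", RemodelerModel.none())
    return RunConfig(template=template, remodeler=remodeler, **kw)


#: canonical experiment geometries: TF site 10-75 bp from the 601NPE on
#: 800-1200 bp templates, internal or end-positioned nucleosome, with the
#: remodeler and reaction-duration class of the corresponding assay.
PRESETS = {
    "unremodeled_sep10": dict(
        template=TemplateSpec(800, 10), remodeler=RemodelerModel.none()),
    "isw1a_short_sep10": dict(
        template=TemplateSpec(800, 10), remodeler=RemodelerModel.isw1a(),
        duration="short"),
    "swisnf_short_sep10": dict(
        template=TemplateSpec(800, 10), remodeler=RemodelerModel.swisnf(),
        duration="short"),
    "isw1a_long_end_sep24": dict(
        template=TemplateSpec(800, 24, end_positioned=True),
        remodeler=RemodelerModel.isw1a(), duration="long"),
    "isw1a_long_end_sep50": dict(
        template=TemplateSpec(800, 50, end_positioned=True),
        remodeler=RemodelerModel.isw1a(), duration="long"),
    "isw1a_long_end_sep75": dict(
        template=TemplateSpec(800, 75, end_positioned=True),
        remodeler=RemodelerModel.isw1a(), duration="long"),
    "swisnf_long_center_sep11": dict(
        template=TemplateSpec(1200, 11), remodeler=RemodelerModel.swisnf(),
        duration="long"),
}


def preset_config(name: str, **overrides) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return _preset(name, **kw)
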