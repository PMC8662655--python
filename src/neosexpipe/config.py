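"""Pipeline configuration: every analysis threshold in one place.

Defaults are the published decision-rule values; any subset can be
overridden from a YAML file or CLI flags (flag > file > default).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .phasing import DeletionConfig, PhasingConfig
from .popgen import PopgenConfig
from .sexlink import ClassifierConfig, HomologyConfig


@dataclass
class TimingConfig:
    tau: float = 70.0       # bootstrap support threshold (%)
    min_aln: int = 700      # minimum trimmed alignment length (bp)
    n_bootstrap: int = 100
    geneconv_alpha: float = 0.05
    geneconv_perms: int = 10_000


@dataclass
class RatesConfig:
    min_len: int = 500      # minimum retained alignment length (bp)
    max_ds: float = 3.0     # saturation cutoff


@dataclass
class PipelineConfig:
    seed: int = 0
    sexlink: ClassifierConfig = field(default_factory=ClassifierConfig)
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    phasing: PhasingConfig = field(default_factory=PhasingConfig)
    deletion: DeletionConfig = field(default_factory=DeletionConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    rates: RatesConfig = field(default_factory=RatesConfig)
    popgen: PopgenConfig = field(default_factory=PopgenConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def dec(klass, payload):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in payload:
                    continue
                val = payload[f.name]
                nested = (f.default_factory()
                          if f.default_factory is not dataclasses.MISSING else None)
                if dataclasses.is_dataclass(nested):
                    val = dec(type(nested), val)
                elif isinstance(f.default, frozenset):
                    val = frozenset(val)
                elif isinstance(f.default, tuple):
                    val = tuple(val)
                kwargs[f.name] = val
            return klass(**kwargs)
        return dec(cls, data or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
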