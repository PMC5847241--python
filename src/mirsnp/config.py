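"""Run configuration shared by the library pipeline and the CLI.

Every tunable has a documented default; a parsed config is echoed verbatim
into the output directory so a run is reproducible from its artifacts alone.
The file format is flat ``key = value`` lines (``#`` comments allowed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

from .duplex import DuplexParams
from .errors import ParameterError
from .mendel import QcThresholds


@dataclass
class RunConfig:
    # pattern discovery
    L: int = 4
    W: int = 6
    min_support: int | None = None      # None -> max(2, 1% of corpus)
    markov_order: int = 2
    n_null: int = 1000                  # simulated null corpora
    min_log_odds: float = math.log(2.0)
    # island calling
    window: int = 25
    min_island_hits: int = 5
    # duplex alignment
    duplex: DuplexParams = field(default_factory=DuplexParams)
    # classification
    epsilon: float = 0.5                # equal-binding score margin
    # SNP intake
    maf_min: float = 0.03
    # QC
    qc: QcThresholds = field(default_factory=QcThresholds)
    removal_policy: str = "trio"
    # randomness
    seed: int = 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.flat_items():
                fh.write(f"{key} = {value}\n")

    def flat_items(self):
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                for sub in dataclasses.fields(value):
                    yield f"{f.name}.{sub.name}", getattr(value, sub.name)
            else:
                yield f.name, value

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                raw[key] = value
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict[str, str]) -> "RunConfig":
        cfg = cls()
        top = {f.name: f for f in dataclasses.fields(cls)}
        duplex_kw: dict = {}
        qc_kw: dict = {}
        for key, value in raw.items():
            if key.startswith("duplex."):
                duplex_kw[key.split(".", 1)[1]] = value
            elif key.startswith("qc."):
                qc_kw[key.split(".", 1)[1]] = value
            elif key in top:
                setattr(cfg, key, _coerce(value, getattr(cfg, key)))
            else:
                raise ParameterError(f"unknown config key {key!r}")
        if duplex_kw:
            base = dataclasses.asdict(cfg.duplex)
            base.update({k: _coerce(v, base[k]) for k, v in duplex_kw.items()
                         if k in base})
            unknown = set(duplex_kw) - set(base)
            if unknown:
                raise ParameterError(f"unknown duplex config keys {sorted(unknown)}")
            cfg.duplex = DuplexParams(**base)
        if qc_kw:
            base = dataclasses.asdict(cfg.qc)
            unknown = set(qc_kw) - set(base)
            if unknown:
                raise ParameterError(f"unknown qc config keys {sorted(unknown)}")
            base.update({k: _coerce(v, base[k]) for k, v in qc_kw.items()})
            cfg.qc = QcThresholds(**base)
        return cfg


def _coerce(value, template):
    if isinstance(value, str):
        value = value.strip()
        if template is None or isinstance(template, int) and not isinstance(template, bool):
            return int(value)
        if isinstance(template, bool):
            return value.lower() in ("1", "true", "yes")
        if isinstance(template, float):
            return float(value)
        return value
    return value
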