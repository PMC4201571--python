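"""Run configuration.

Defaults reproduce the reference search parameters: 1.5 Da precursor
tolerance, 0.3 Da fragment tolerance / XCorr bin width, 12 Da candidate
window, +1 product ions with water/ammonia losses, monoisotopic masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class RunConfig:
    prec_tol_da: float = 1.5
    frag_tol_da: float = 0.3
    window_da: float = 12.0
    bin_width: float = 0.3
    k: int = 1000
    seed: int = 0
    max_var: int = 3
    mods: tuple = ()  # names from mass_model.STANDARD_MODS to enable
    prefilter: bool = False
    top_n: int = 8
    top_peaks_lambda: int = 40
    charges: tuple = (1,)
    losses: bool = True
    rounding: int = 6  # decimals for homeometric indicator equality
    mass_tol_da: float = 1.5  # homeometric mass link distance

    def __post_init__(self) -> None:
        for name in ("prec_tol_da", "frag_tol_da", "window_da", "bin_width", "mass_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {line_no}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                raw[key] = val
        kw = {}
        by_name = {f.name: f for f in fields(cls)}
        for key, val in raw.items():
            if key not in by_name:
                raise ValueError(f"unknown configuration key {key!r}")
            default = getattr(cls, key, None) or by_name[key].default
            if key == "mods":
                kw[key] = tuple(s for s in val.split(",") if s)
            elif key == "charges":
                kw[key] = tuple(int(s) for s in val.split(",") if s)
            elif isinstance(default, bool):
                kw[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kw[key] = int(val)
            elif isinstance(default, float):
                kw[key] = float(val)
            else:
                kw[key] = val
        return cls(**kw)
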