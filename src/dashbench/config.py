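"""Scenario configuration for the depletion benchmark.

A scenario is a flat ``key = value`` text file describing one paired
untreated/DASHed simulation: library geometry (cells, empty droplets,
genes), the contaminant load in cells and in the ambient pool, library-size
distributions, amplification noise, depletion efficiency and the sequencing
read budget.  The ``bench-default`` scenario shipped with the package
encodes the benchmark operating point: ~60% of cell UMIs and ~95% of
ambient UMIs belonging to a single contaminant transcript, with a
per-molecule cut probability of 0.999.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union


class ConfigError(ValueError):
    """Raised when a scenario file is malformed or violates the schema."""


@dataclass
class BenchConfig:
    """Parameters of one paired-library benchmark scenario.

    Fractions and probabilities must lie in [0, 1]; counts must be positive.
    A seed is always present: every source of randomness in the package
    flows from it.
    """

    # library geometry
    n_cells: int = 2000
    n_empty: int = 5000
    n_genes: int = 1000

    # truth model: cell types and markers
    n_types: int = 8
    rare_type_prop: float = 0.02
    markers_per_type: int = 25
    marker_fold: float = 8.0
    program_sigma: float = 1.0          # log-normal spread of baseline gene abundances
    contaminant_name: str = "16S"
    stem_marker_name: str = "piwi-1"
    stem_marker_share: float = 0.05     # marker share of the program in stem types
    n_nonstem_types: int = 1

    # per-barcode molecule counts (log-normal, parameterized by median)
    cell_median_molecules: float = 2000.0
    cell_sigma_log: float = 0.35
    empty_median_molecules: float = 400.0
    empty_sigma_log: float = 0.6

    # contaminant load
    p_contaminant: float = 0.60         # mean per-cell contaminant molecule fraction
    p_concentration: float = 200.0      # Beta concentration of the per-cell fraction
    ambient_contaminant: float = 0.95   # contaminant weight of the ambient profile

    # amplification / sequencing
    sigma0: float = 0.15                # per-cycle amplification noise scale
    pre_cycles: int = 10
    post_cycles: int = 10
    epsilon: float = 0.999              # per-molecule cut probability of the depletion
    total_reads: int = 6_000_000

    seed: int = 0

    _FRACTIONS = (
        "rare_type_prop", "stem_marker_share", "p_contaminant",
        "ambient_contaminant", "epsilon",
    )
    _POSITIVE_COUNTS = (
        "n_cells", "n_empty", "n_genes", "n_types", "markers_per_type",
        "pre_cycles", "total_reads",
    )

    def validate(self) -> "BenchConfig":
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in self._POSITIVE_COUNTS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.post_cycles < 0:
            raise ConfigError("post_cycles must be >= 0")
        for name in ("cell_median_molecules", "empty_median_molecules",
                     "marker_fold", "p_concentration", "program_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("cell_sigma_log", "empty_sigma_log", "sigma0"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if not 0 <= self.n_nonstem_types < self.n_types:
            raise ConfigError("n_nonstem_types must be in [0, n_types)")
        if self.n_types * self.markers_per_type >= self.n_genes:
            raise ConfigError(
                f"n_types*markers_per_type = {self.n_types * self.markers_per_type} "
                f"marker genes do not fit in n_genes = {self.n_genes}"
            )
        if self.rare_type_prop >= 1.0 / self.n_types:
            raise ConfigError("rare_type_prop must be < 1/n_types")
        return self

    def replace(self, **kw) -> "BenchConfig":
        return dataclasses.replace(self, **kw).validate()

    # ---- flat key=value serialization -------------------------------------

    def to_file(self, path: Union[str, Path]) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "BenchConfig":
        text = Path(path).read_text()
        return cls.from_text(text, source=str(path))

    @classmethod
    def from_text(cls, text: str, source: str = "<config>") -> "BenchConfig":
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        kw = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{source}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ConfigError(f"{source}:{lineno}: unknown parameter {key!r}")
            try:
                kw[key] = casts[types[key]](value)
            except ValueError as exc:
                raise ConfigError(
                    f"{source}:{lineno}: cannot parse {key} = {value!r}"
                ) from exc
        return cls(**kw).validate()


def load_scenario(name_or_path: Union[str, Path]) -> BenchConfig:
    """Load a scenario by shipped name (e.g. ``bench-default``) or file path."""
    p = Path(name_or_path)
    if p.exists():
        return BenchConfig.from_file(p)
    res = importlib.resources.files("dashbench").joinpath(f"data/{name_or_path}.cfg")
    if res.is_file():
        return BenchConfig.from_text(res.read_text(), source=str(name_or_path))
    raise ConfigError(f"no such scenario or file: {name_or_path}")
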