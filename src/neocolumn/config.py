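"""Column configuration: schema, YAML loading, and parameter-table I/O.

A column config bundles everything needed to build and run a column:

* ``architecture`` — neuron counts per layer and cell class;
* ``aeif_tables`` — one membrane-parameter table per species (or condition),
  keyed by layer then cell class;
* ``synapses`` — kernel constants per receptor (AMPA, NMDA, GABAA);
* ``stp`` — Tsodyks–Markram constants, shared by all connections;
* ``connectivity`` — an ordered rule list resolving to a pairwise
  connection-probability matrix over (layer, class) blocks;
* ``background_currents`` — tonic drive for excitatory cells and interneurons;
* ``stimulus`` / ``assay`` / ``simulation`` — the persistent-activity assay
  protocol and integrator settings.

Unknown keys anywhere in the file are rejected.  Parameter tables can also
be imported from CSV with one row per (layer, class) and columns
``C, g_L, E_L, V_r, V_th, Delta_T, tau_w, a, b``.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .neuron import AEIFParams
from .synapse import Receptor, STPParams, SynapseParams

__all__ = [
    "ColumnConfig",
    "load_config",
    "default_config",
    "load_aeif_table_csv",
    "write_aeif_table_csv",
]

LAYERS = ("L2/3", "L5", "L6")
CELL_CLASSES = ("PC", "LL-IN", "BPC", "LBC", "MC")
EXCITATORY_CLASSES = frozenset({"PC"})

AEIF_FIELDS = ("C", "g_L", "E_L", "V_r", "V_th", "Delta_T", "tau_w", "a", "b")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AEIFBlock(_Strict):
    C: float
    g_L: float
    E_L: float
    V_r: float
    V_th: float
    Delta_T: float
    tau_w: float
    a: float
    b: float

    def to_params(self) -> AEIFParams:
        return AEIFParams(**self.model_dump())


class SynapseBlock(_Strict):
    g_max: float
    E_rev: float
    tau_on: float
    tau_off: float
    tau_D: float = 1.0

    def to_params(self, receptor: Receptor) -> SynapseParams:
        return SynapseParams(receptor=receptor, **self.model_dump())


class STPBlock(_Strict):
    U: float = 0.25
    tau_facil: float = 500.0
    tau_rec: float = 300.0

    def to_params(self) -> STPParams:
        return STPParams(**self.model_dump())


class ConnectivityRule(_Strict):
    """One wildcard rule; ``null`` (None) fields match any layer/class.
    Later rules override earlier ones."""

    src_layer: Optional[str] = None
    src_class: Optional[str] = None
    tgt_layer: Optional[str] = None
    tgt_class: Optional[str] = None
    p: float = Field(ge=0.0, le=1.0)

    def matches(self, src: Tuple[str, str], tgt: Tuple[str, str]) -> bool:
        return (
            (self.src_layer is None or self.src_layer == src[0])
            and (self.src_class is None or self.src_class == src[1])
            and (self.tgt_layer is None or self.tgt_layer == tgt[0])
            and (self.tgt_class is None or self.tgt_class == tgt[1])
        )


class WeightRule(_Strict):
    """Multiplicative conductance scale for matching projections."""

    src_layer: Optional[str] = None
    src_class: Optional[str] = None
    tgt_layer: Optional[str] = None
    tgt_class: Optional[str] = None
    scale: float = Field(ge=0.0)

    def matches(self, src: Tuple[str, str], tgt: Tuple[str, str]) -> bool:
        return ConnectivityRule.matches(self, src, tgt)  # type: ignore[arg-type]


class Connectivity(_Strict):
    default: float = Field(default=0.0, ge=0.0, le=1.0)
    rules: List[ConnectivityRule] = Field(default_factory=list)
    weight_rules: List[WeightRule] = Field(default_factory=list)
    allow_autapses: bool = False

    def probability(self, src: Tuple[str, str], tgt: Tuple[str, str]) -> float:
        p = self.default
        for rule in self.rules:
            if rule.matches(src, tgt):
                p = rule.p
        return p

    def weight_scale(self, src: Tuple[str, str], tgt: Tuple[str, str]) -> float:
        s = 1.0
        for rule in self.weight_rules:
            if rule.matches(src, tgt):
                s = rule.scale
        return s


class BackgroundCurrents(_Strict):
    excitatory: float = 250.0
    inhibitory: float = 200.0


class StimulusConfig(_Strict):
    onset: float = 201.0
    duration: float = 99.0
    amplitude: float = 2000.0
    mode: Literal["pulse", "poisson50"] = "poisson50"
    poisson_rate: float = 50.0
    pulse_width: float = 1.0


class AssayConfig(_Strict):
    t_end: float = 300.0
    baseline_window: Tuple[float, float] = (100.0, 200.0)
    pa_window: Tuple[float, float] = (200.0, 300.0)
    decode_window: Tuple[float, float] = (202.0, 300.0)
    n_repeats: int = 9


class SimulationConfig(_Strict):
    dt: float = 0.05
    exp_clamp: float = 10.0
    canonical_exp_term: bool = False


class Architecture(_Strict):
    layers: Dict[str, Dict[str, int]]

    @field_validator("layers")
    @classmethod
    def _check_layers(cls, v):
        for layer, classes in v.items():
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
            for cls_name, count in classes.items():
                if cls_name not in CELL_CLASSES:
                    raise ValueError(
                        f"unknown cell class {cls_name!r}; expected one of {CELL_CLASSES}"
                    )
                if count < 0:
                    raise ValueError(f"negative count for {layer} {cls_name}")
        return v

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self.layers.values())

    def blocks(self) -> List[Tuple[str, str, int]]:
        """(layer, class, count) in canonical order: layers L2/3, L5, L6 and
        classes PC, LL-IN, BPC, LBC, MC; PCs of L2/3 therefore occupy the
        first ids (1-based, row-major image order)."""
        out = []
        for layer in LAYERS:
            classes = self.layers.get(layer, {})
            for cls_name in CELL_CLASSES:
                if cls_name in classes and classes[cls_name] > 0:
                    out.append((layer, cls_name, classes[cls_name]))
        return out


class ColumnConfig(_Strict):
    architecture: Architecture
    aeif_tables: Dict[str, Dict[str, Dict[str, AEIFBlock]]]
    synapses: Dict[str, SynapseBlock]
    stp: STPBlock = Field(default_factory=STPBlock)
    connectivity: Connectivity
    background_currents: BackgroundCurrents = Field(default_factory=BackgroundCurrents)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    assay: AssayConfig = Field(default_factory=AssayConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @model_validator(mode="after")
    def _check(self):
        for name in ("AMPA", "NMDA", "GABAA"):
            if name not in self.synapses:
                raise ValueError(f"synapses section must define {name}")
        for species, table in self.aeif_tables.items():
            for layer in table:
                if layer not in LAYERS:
                    raise ValueError(f"unknown layer {layer!r} in table {species!r}")
                for cls_name in table[layer]:
                    if cls_name not in CELL_CLASSES:
                        raise ValueError(
                            f"unknown cell class {cls_name!r} in table {species!r}"
                        )
        return self

    def synapse_params(self, receptor: Receptor | str) -> SynapseParams:
        receptor = Receptor(receptor)
        return self.synapses[receptor.value].to_params(receptor)

    def aeif_params(self, species: str, layer: str, cell_class: str) -> AEIFParams:
        """Resolve the membrane parameters of one (layer, class) cell group.

        Large basket cells (LBC) default to the pyramidal-cell entry of their
        layer (they are electrophysiologically PC-like); Martinotti and
        bipolar cells default to the layer's local interneuron (LL-IN) entry
        when no dedicated row is provided.
        """
        table = self.aeif_tables[species]
        if layer not in table:
            raise KeyError(f"table {species!r} has no layer {layer!r}")
        entry = table[layer].get(cell_class)
        if entry is None:
            fallback = {"LBC": "PC", "MC": "LL-IN", "BPC": "LL-IN"}.get(cell_class)
            if fallback is not None:
                entry = table[layer].get(fallback)
            if entry is None:
                raise KeyError(
                    f"table {species!r} lacks an entry for ({layer}, {cell_class})"
                )
        return entry.to_params()

    def species(self) -> List[str]:
        return list(self.aeif_tables)


def load_config(path: str | Path) -> ColumnConfig:
    """Load and validate a YAML column config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ColumnConfig.model_validate(raw)


def default_config() -> ColumnConfig:
    """The bundled two-species (rodent, human) default column."""
    ref = importlib.resources.files("neocolumn.data") / "default_column.yaml"
    return ColumnConfig.model_validate(yaml.safe_load(ref.read_text()))


def load_aeif_table_csv(path: str | Path) -> Dict[str, Dict[str, AEIFBlock]]:
    """Read a membrane-parameter table from CSV.

    Expected columns: ``layer, cell_class, C, g_L, E_L, V_r, V_th, Delta_T,
    tau_w, a, b`` with one row per (layer, class).
    """
    df = pd.read_csv(path)
    required = {"layer", "cell_class", *AEIF_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter CSV missing columns: {sorted(missing)}")
    table: Dict[str, Dict[str, AEIFBlock]] = {}
    for _, row in df.iterrows():
        block = AEIFBlock(**{f: float(row[f]) for f in AEIF_FIELDS})
        table.setdefault(str(row["layer"]), {})[str(row["cell_class"])] = block
    return table


def write_aeif_table_csv(table: Dict[str, Dict[str, AEIFBlock]], path: str | Path) -> None:
    rows = []
    for layer, classes in table.items():
        for cls_name, block in classes.items():
            rows.append({"layer": layer, "cell_class": cls_name, **block.model_dump()})
    pd.DataFrame(rows).to_csv(path, index=False)
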