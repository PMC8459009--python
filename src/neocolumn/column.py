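"""Construction of the layered column network.

The default column has 2,000 neurons across three layers (L2/3, L5, L6) and
five cell classes: pyramidal cells (PC, excitatory), local-layer
interneurons (LL-IN), bipolar cells (BPC, cross-layer interneurons), large
basket cells (LBC) and Martinotti cells (MC, both long-range interneurons).
The 900 L2/3 PCs occupy ids 1–900 (1-based, row-major image order), which
fixes the mapping between the 30x30 stimulus image and the network.

Every ordered (pre, post) pair with pre != post is connected independently
with the probability configured for its (layer, class) block pair.
Excitatory sources project through AMPA + NMDA, inhibitory sources through
GABA_A.  Construction is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import (
    CELL_CLASSES,
    EXCITATORY_CLASSES,
    LAYERS,
    AEIF_FIELDS,
    AEIFBlock,
    ColumnConfig,
)
from .neuron import AEIFParams
from .synapse import STPParams, SynapseParams

__all__ = ["ColumnNetwork", "build_column", "assign_parameters", "RECEPTOR_ORDER"]

RECEPTOR_ORDER = ("AMPA", "NMDA", "GABAA")


@dataclass
class ColumnNetwork:
    """A fully parameterized column ready to simulate.

    Neurons are listed in a DataFrame (id, layer, cell_class, excitatory);
    membrane parameters live in ``aeif`` as an (N, 9) array in the order
    C, g_L, E_L, V_r, V_th, Delta_T, tau_w, a, b.  Synapses are stored in
    compressed sparse row form by presynaptic neuron: ``syn_post[j]`` for j
    in ``syn_indptr[i]:syn_indptr[i+1]`` are the 0-based targets of neuron
    i+1, and ``syn_weight[j, r]`` the peak conductance (nS) contributed
    through receptor r (AMPA, NMDA, GABAA order; zero where inapplicable).
    """

    neurons: pd.DataFrame
    aeif: np.ndarray
    background: np.ndarray
    syn_indptr: np.ndarray
    syn_post: np.ndarray
    syn_weight: np.ndarray
    synapse_params: Dict[str, SynapseParams]
    stp_params: STPParams
    seed: int
    species: str = ""
    config_hash: str = ""
    exp_clamp: float = 10.0
    canonical_exp_term: bool = False

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        return len(self.syn_post)

    def ids_of(self, layer: str, cell_class: str) -> np.ndarray:
        sel = (self.neurons["layer"] == layer) & (self.neurons["cell_class"] == cell_class)
        return self.neurons.loc[sel, "id"].to_numpy()

    def synapse_pairs(self) -> np.ndarray:
        """(n_synapses, 2) array of 1-based (pre, post) ids."""
        pre = np.repeat(
            np.arange(1, self.n_neurons + 1),
            np.diff(self.syn_indptr),
        )
        return np.column_stack([pre, self.syn_post + 1])

    def params_of(self, neuron_id: int) -> AEIFParams:
        row = self.aeif[neuron_id - 1]
        return AEIFParams(**dict(zip(AEIF_FIELDS, row)))


def _config_hash(config: ColumnConfig) -> str:
    blob = config.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_column(
    config: ColumnConfig,
    species: Optional[str] = None,
    seed: int = 0,
    table: Optional[Dict[str, Dict[str, AEIFBlock]]] = None,
) -> ColumnNetwork:
    """Build a column: draw the random connectivity, then assign the
    membrane parameters of ``species`` (or an explicit ``table``).

    The same (config, seed) always yields the identical synapse list; the
    species table only affects per-neuron parameters, so the rodent and
    human columns built from one seed share their wiring exactly.
    """
    arch = config.architecture
    blocks = arch.blocks()
    total = arch.total
    if total <= 0:
        raise ValueError("architecture has no neurons")

    layers: List[str] = []
    classes: List[str] = []
    for layer, cls_name, count in blocks:
        layers.extend([layer] * count)
        classes.extend([cls_name] * count)
    excitatory = np.array([c in EXCITATORY_CLASSES for c in classes])
    neurons = pd.DataFrame(
        {
            "id": np.arange(1, total + 1),
            "layer": layers,
            "cell_class": classes,
            "excitatory": excitatory,
        }
    )

    # block index ranges (0-based, contiguous by construction)
    starts: Dict[Tuple[str, str], Tuple[int, int]] = {}
    pos = 0
    for layer, cls_name, count in blocks:
        starts[(layer, cls_name)] = (pos, pos + count)
        pos += count

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    conn = config.connectivity
    g_ampa = config.synapses["AMPA"].g_max
    g_nmda = config.synapses["NMDA"].g_max
    g_gaba = config.synapses["GABAA"].g_max

    pre_list: List[np.ndarray] = []
    post_list: List[np.ndarray] = []
    scale_list: List[np.ndarray] = []
    for src_layer, src_class, _ in blocks:
        s0, s1 = starts[(src_layer, src_class)]
        for tgt_layer, tgt_class, _ in blocks:
            t0, t1 = starts[(tgt_layer, tgt_class)]
            p = conn.probability((src_layer, src_class), (tgt_layer, tgt_class))
            if p <= 0:
                continue
            mask = rng.random((s1 - s0, t1 - t0)) < p
            if not conn.allow_autapses and (src_layer, src_class) == (tgt_layer, tgt_class):
                np.fill_diagonal(mask, False)
            pre_idx, post_idx = np.nonzero(mask)
            if pre_idx.size == 0:
                continue
            scale = conn.weight_scale((src_layer, src_class), (tgt_layer, tgt_class))
            pre_list.append(pre_idx.astype(np.int64) + s0)
            post_list.append(post_idx.astype(np.int64) + t0)
            scale_list.append(np.full(pre_idx.size, scale))

    if pre_list:
        pre = np.concatenate(pre_list)
        post = np.concatenate(post_list)
        scale = np.concatenate(scale_list)
        order = np.lexsort((post, pre))
        pre, post, scale = pre[order], post[order], scale[order]
    else:
        pre = np.empty(0, dtype=np.int64)
        post = np.empty(0, dtype=np.int64)
        scale = np.empty(0, dtype=np.float64)

    indptr = np.zeros(total + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    indptr = np.cumsum(indptr)

    weight = np.zeros((len(post), 3))
    exc_pre = excitatory[pre]
    weight[exc_pre, 0] = scale[exc_pre] * g_ampa
    weight[exc_pre, 1] = scale[exc_pre] * g_nmda
    weight[~exc_pre, 2] = scale[~exc_pre] * g_gaba

    network = ColumnNetwork(
        neurons=neurons,
        aeif=np.zeros((total, 9)),
        background=np.zeros(total),
        syn_indptr=indptr,
        syn_post=post.astype(np.int64),
        syn_weight=weight,
        synapse_params={r: config.synapse_params(r) for r in RECEPTOR_ORDER},
        stp_params=config.stp.to_params(),
        seed=seed,
        config_hash=_config_hash(config),
        exp_clamp=config.simulation.exp_clamp,
        canonical_exp_term=config.simulation.canonical_exp_term,
    )
    if table is not None or species is not None:
        assign_parameters(network, config, species=species, table=table)
    return network


def assign_parameters(
    network: ColumnNetwork,
    config: ColumnConfig,
    species: Optional[str] = None,
    table: Optional[Dict[str, Dict[str, AEIFBlock]]] = None,
) -> ColumnNetwork:
    """Assign per-neuron membrane parameters and background currents in
    place from a species table of the config (or an explicit table dict).

    LBC rows may be absent from the table: large basket cells then carry
    the PC parameters of their layer.  Background currents follow the
    excitatory/interneuron split of the config.
    """
    if table is not None:
        tmp = config.model_copy(deep=True)
        tmp.aeif_tables = {"__explicit__": table}
        cfg, sp = tmp, "__explicit__"
    else:
        if species is None:
            raise ValueError("either species or table must be given")
        if species not in config.aeif_tables:
            raise KeyError(f"no parameter table for species {species!r}")
        cfg, sp = config, species

    cache: Dict[Tuple[str, str], np.ndarray] = {}
    for (layer, cls_name), group in network.neurons.groupby(
        ["layer", "cell_class"], sort=False
    ):
        params = cfg.aeif_params(sp, layer, cls_name)
        row = np.array([getattr(params, f) for f in AEIF_FIELDS])
        cache[(layer, cls_name)] = row
        idx = group.index.to_numpy()
        network.aeif[idx] = row
        bg = (
            config.background_currents.excitatory
            if cls_name in EXCITATORY_CLASSES
            else config.background_currents.inhibitory
        )
        network.background[idx] = bg
    network.species = species or "__explicit__"
    return network
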