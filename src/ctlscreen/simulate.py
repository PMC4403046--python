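"""Synthetic dual-condition cytotoxicity screens with known planted effects.

The generator emulates the experiment the analysis pipeline was designed for:
a 520-pool siRNA library screened in three luciferase-readout screens, each
with two replicate plate sets exposed to cytotoxic T lymphocytes (CTLs, the
*toxicity* set) and two incubated without them (the *viability* set), plus an
orthogonal ATP-readout viability screen with no CTLs at all.

Well intensities follow a log-additive (multiplicative on the raw scale)
model. For a sample well targeting gene *g* on screen *s*:

    log2 I = b + plate + row + col + v_g + [with_ctl] * (k + m_{g,s}) + eps

where ``b`` is the baseline log2 luminescence, ``plate``/``row``/``col`` are
systematic plate and spatial effects, ``v_g`` is the gene's intrinsic
(condition-independent) viability effect, ``k`` is the global CTL kill effect
applied to every with-CTL well, ``m_{g,s}`` is the gene's immune-modulation
effect (negative for an immune suppressor: its knockdown enhances killing and
lowers the with-CTL signal), and ``eps ~ N(0, sigma)``. The ATP-readout
condition ignores ``k`` and ``m`` entirely (no CTLs present).

Cross-screen heterogeneity of immune modulation — the screens intentionally
differ in CTL source and luciferase delivery — is modelled as
``m_{g,s} = m_g * (1 + h * eta_{g,s})`` with per-(gene, screen) standard
normal jitter ``eta`` scaled by ``h`` in [0, 1].

Planted gene classes mirror the screen's biological controls: immune
*suppressors* (PD-L1-like: v = 0, m < 0), immune *activators* (v = 0, m > 0),
*lethals* (UBC/PLK1-like: v strongly negative, m = 0) and *proviability*
genes (v > 0, m = 0). All remaining genes are *neutral*: no immune modulation
(m = 0) and a small background intrinsic-viability effect
``v ~ N(0, background_v_sd)``, reflecting that real siRNA pools always
perturb viability somewhat; set ``background_v_sd = 0`` for an idealised
library in which neutral genes have v = 0 exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import LibraryDesign, PLATE_ROWS, PLATE_COLS, default_library
from .io import ScreenDataset, WELL_COLUMNS, write_table, read_table

GENE_CLASSES = ("neutral", "suppressor", "activator", "lethal", "proviability")


class SimConfigError(ValueError):
    """Raised for an unsatisfiable simulation configuration."""


@dataclass
class SimConfig:
    """Tunable parameters of the synthetic screen.

    Effects are log2 fold changes of raw intensity; ``*_effect`` ranges are
    (lo, hi) magnitude bounds sampled uniformly per planted gene.
    """

    baseline_log2: float = 10.0          # b: log2 RLU of an unperturbed well
    kill_effect: float = -0.5            # k: global CTL kill, all with_ctl wells
    noise_sd: float = 0.3                # sigma of eps, log2 scale
    plate_effect_sd: float = 0.15        # per plate-instance log2 offset SD
    row_gradient: float = 0.0            # linear row effect amplitude (+-)
    col_gradient: float = 0.0            # linear column effect amplitude (+-)
    heterogeneity: float = 0.2           # h: cross-screen jitter on m_g
    background_v_sd: float = 0.6         # intrinsic viability SD of neutral genes
    n_suppressors: int = 10
    n_activators: int = 10
    n_lethals: int = 5
    n_proviability: int = 0
    suppressor_effect: tuple[float, float] = (1.25, 2.0)   # |m|, applied negative
    activator_effect: tuple[float, float] = (1.25, 2.0)    # |m|, applied positive
    lethal_effect: tuple[float, float] = (3.5, 4.5)        # |v|, applied negative
    proviability_effect: tuple[float, float] = (1.5, 2.5)  # |v|, applied positive
    control_lethal_v: float = -4.0
    control_suppressor_m: float = -1.5
    fluc_log2_offset: float = -8.0       # luciferase-targeting control background
    replicates: int = 2
    screens: tuple[str, ...] = ("s1", "s2", "s3")
    ctg_screen_id: str = "s4"
    seed: int = 0

    def validate(self, library: LibraryDesign | None = None) -> "SimConfig":
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise SimConfigError("heterogeneity must lie in [0, 1]")
        if self.background_v_sd < 0:
            raise SimConfigError("background_v_sd must be >= 0")
        if self.replicates < 1:
            raise SimConfigError("need at least one replicate")
        counts = (
            self.n_suppressors,
            self.n_activators,
            self.n_lethals,
            self.n_proviability,
        )
        if any(c < 0 for c in counts):
            raise SimConfigError("planted counts must be nonnegative")
        if library is not None and sum(counts) > library.n_genes:
            raise SimConfigError(
                f"{sum(counts)} planted genes exceed library size {library.n_genes}"
            )
        return self


@dataclass
class SimulationTruth:
    """Planted per-gene effects: the ground truth for recovery tests.

    ``table`` is indexed by gene_id with columns ``class_label``, ``v`` (the
    intrinsic viability effect) and ``m`` (the base immune-modulation
    effect); ``modulation`` holds the realised per-screen effects m_{g,s}.
    """

    table: pd.DataFrame
    modulation: pd.DataFrame  # gene x screen

    def genes_of_class(self, class_label: str) -> list[str]:
        return list(self.table.index[self.table["class_label"] == class_label])

    def to_frame(self) -> pd.DataFrame:
        mod = self.modulation.rename(columns=lambda s: f"m_{s}")
        return pd.concat([self.table, mod], axis=1)

    def write(self, path: str | Path) -> Path:
        return write_table(self.to_frame().rename_axis("gene_id"), path)

    @classmethod
    def read(cls, path: str | Path) -> "SimulationTruth":
        df = read_table(path)
        mcols = [c for c in df.columns if c.startswith("m_") and c != "m"]
        mod = df[mcols].rename(columns=lambda c: c[2:])
        return cls(table=df[["class_label", "v", "m"]], modulation=mod)


def generate_truth(
    library: LibraryDesign, config: SimConfig, seed: int | None = None
) -> SimulationTruth:
    """Draw the planted effect table for one simulated experiment.

    Deterministic under ``seed`` (defaults to ``config.seed``); planted
    classes are disjoint; cross-screen modulation follows
    ``m_{g,s} = m_g * (1 + h * eta_{g,s})``.
    """
    config.validate(library)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = np.asarray(library.genes)
    n = len(genes)

    perm = rng.permutation(n)
    counts = {
        "suppressor": config.n_suppressors,
        "activator": config.n_activators,
        "lethal": config.n_lethals,
        "proviability": config.n_proviability,
    }
    classes = np.full(n, "neutral", dtype=object)
    pos = 0
    planted_idx: dict[str, np.ndarray] = {}
    for cls, cnt in counts.items():
        planted_idx[cls] = perm[pos : pos + cnt]
        classes[planted_idx[cls]] = cls
        pos += cnt

    # background intrinsic viability, drawn for all genes so the number of
    # RNG draws is independent of the planted counts, then overridden
    v = rng.normal(0.0, config.background_v_sd, size=n) if config.background_v_sd > 0 else np.zeros(n)
    m = np.zeros(n)

    m[planted_idx["suppressor"]] = -rng.uniform(*config.suppressor_effect, size=counts["suppressor"])
    m[planted_idx["activator"]] = rng.uniform(*config.activator_effect, size=counts["activator"])
    v[planted_idx["suppressor"]] = 0.0
    v[planted_idx["activator"]] = 0.0
    v[planted_idx["lethal"]] = -rng.uniform(*config.lethal_effect, size=counts["lethal"])
    m[planted_idx["lethal"]] = 0.0
    v[planted_idx["proviability"]] = rng.uniform(*config.proviability_effect, size=counts["proviability"])
    m[planted_idx["proviability"]] = 0.0

    eta = rng.standard_normal((n, len(config.screens)))
    mod = m[:, None] * (1.0 + config.heterogeneity * eta)

    table = pd.DataFrame(
        {"class_label": classes, "v": v, "m": m}, index=pd.Index(genes, name="gene_id")
    )
    modulation = pd.DataFrame(mod, index=table.index, columns=list(config.screens))
    return SimulationTruth(table=table, modulation=modulation)


def _spatial_effects(layout: pd.DataFrame, config: SimConfig) -> np.ndarray:
    row = layout["row"].to_numpy()
    col = layout["col"].to_numpy()
    n_rows = len(PLATE_ROWS)
    r_eff = config.row_gradient * (2.0 * row / (n_rows - 1) - 1.0)
    c_eff = config.col_gradient * (2.0 * (col - 1) / (PLATE_COLS - 1) - 1.0)
    return r_eff + c_eff


def generate_screen(
    library: LibraryDesign,
    truth: SimulationTruth,
    config: SimConfig,
    seed: int | None = None,
) -> ScreenDataset:
    """Realise the well-level intensity model for every screen and replicate.

    The noise stream is drawn in a fixed well order that does not depend on
    the truth values, so re-running with the same seed but a perturbed truth
    changes only the affected means (monotonicity in the planted effects).
    """
    config.validate(library)
    if not set(library.genes) <= set(truth.table.index):
        raise SimConfigError("truth table does not cover the library")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    layout = library.plate_layout()
    spatial = _spatial_effects(layout, config)
    is_sample = (layout["content"] == "sample").to_numpy()
    is_fluc = (layout["content"] == "control_fluc").to_numpy()

    v = np.zeros(len(layout))
    m_base = np.zeros(len(layout))
    gene_ids = layout["gene_id"].to_numpy()
    v[is_sample] = truth.table.loc[gene_ids[is_sample], "v"].to_numpy()
    v[layout["content"].to_numpy() == "control_lethal"] = config.control_lethal_v
    m_base[layout["content"].to_numpy() == "control_suppressor"] = config.control_suppressor_m

    instances: list[tuple[str, str, int]] = []
    for screen in config.screens:
        for cond in ("with_ctl", "without_ctl"):
            for rep in range(1, config.replicates + 1):
                instances.append((screen, cond, rep))
    for rep in range(1, config.replicates + 1):
        instances.append((config.ctg_screen_id, "ctg", rep))

    b = config.baseline_log2
    frames = []
    for screen, cond, rep in instances:
        for plate_id, grp_idx in layout.groupby("plate_id", sort=True).groups.items():
            idx = np.asarray(grp_idx)
            plate_eff = rng.normal(0.0, config.plate_effect_sd) if config.plate_effect_sd > 0 else 0.0
            eps = rng.normal(0.0, config.noise_sd, size=len(idx)) if config.noise_sd > 0 else np.zeros(len(idx))

            log2_i = b + plate_eff + spatial[idx] + v[idx] + eps
            if cond == "with_ctl":
                m = m_base[idx].copy()
                samp = is_sample[idx]
                m[samp] = truth.modulation.loc[gene_ids[idx][samp], screen].to_numpy()
                log2_i = log2_i + config.kill_effect + m
            # luciferase-targeting control: signal at fixed background,
            # independent of condition and plate effects
            fl = is_fluc[idx]
            log2_i[fl] = b + config.fluc_log2_offset + eps[fl]

            frames.append(
                pd.DataFrame(
                    {
                        "screen_id": screen,
                        "condition": cond,
                        "replicate": rep,
                        "plate_id": plate_id,
                        "well": layout.loc[idx, "well"].to_numpy(),
                        "content": layout.loc[idx, "content"].to_numpy(),
                        "gene_id": layout.loc[idx, "gene_id"].to_numpy(),
                        "intensity": np.exp2(log2_i),
                    }
                )
            )

    wells = pd.concat(frames, ignore_index=True)[list(WELL_COLUMNS)]
    ds = ScreenDataset(
        wells=wells,
        library=library,
        provenance={
            "generator": "ctlscreen.simulate",
            "seed": int(config.seed if seed is None else seed),
            "config": asdict(config),
        },
    )
    return ds.validate(expected_replicates=config.replicates)


def simulate_experiment(
    config: SimConfig | None = None,
    library: LibraryDesign | None = None,
    seed: int | None = None,
) -> tuple[ScreenDataset, SimulationTruth]:
    """Convenience wrapper: default library + truth + screens in one call.

    A single master seed (``seed`` or ``config.seed``) is split into
    independent child streams for the truth draw and the well noise.
    """
    config = config or SimConfig()
    library = library or default_library()
    master = config.seed if seed is None else seed
    truth_seed, screen_seed = np.random.SeedSequence(master).generate_state(2) % (2**31)
    truth = generate_truth(library, config, seed=int(truth_seed))
    dataset = generate_screen(library, truth, config, seed=int(screen_seed))
    return dataset, truth
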