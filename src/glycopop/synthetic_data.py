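"""Ground-truthed synthetic glycopeptide populations, spectra and runs.

Everything the pipeline consumes can be simulated here with known
truth: log-series-skewed glycoform populations on shared tryptic
peptide backbones (IgG Fc glycopeptides by default), MS/MS spectra
carrying oxonium ions and Y-ion ladders, DDA runs with replicate
scans, wide-window DIA runs (MS1 + two 600 Da windows), and an
endoglycosidase truncation time course in which intact glycoforms
collapse onto HexNAc(1) ± core-fucose products.

The fragment intensity model is deliberately simple: peak weights are
linear in residue counts, modulated by a two-parameter collision-
energy weighting (low energy favours neutral-loss Y ions; high energy
favours oxonium and Y1 ions) and by terminal-residue exposure (hexose
oxonium ions come predominantly from mannose-terminated structures,
while galactose in complex-type antennae appears mainly in the
Hex+HexNAc 366.14 series).  Chromatography is Gaussian; glycoforms of
one backbone co-elute, with sialylated species retained ~2 minutes
longer, as observed for IgG glycopeptides on reversed phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .biosynthesis import BiosynthesisRules
from .glycan_model import (
    DEFAULT_TABLE,
    ISOTOPE_SPACING,
    GlycanComposition,
    GlycopeptideIon,
    MonosaccharideTable,
    format_composition,
    oxonium_mz,
    parse_composition,
    y_ion_ladder,
)
from .spectra_io import Run, Spectrum

HUMAN_IGG1_BACKBONE = "EEQYNSTYR"
MOUSE_BACKBONES = ("EEQINSTFR", "EDYNSTLR", "EAQYNSTFR")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; a fixed seed gives identical output."""

    seed: int = 7
    peptides: Tuple[str, ...] = (HUMAN_IGG1_BACKBONE,)
    charge: int = 2
    # population model
    fisher_alpha: float = 5.0
    population_size: int = 1000
    # noise model
    mz_jitter_sd: float = 0.003  # Da, fragment and precursor m/z
    intensity_cv: float = 0.15
    noise_peaks: float = 15.0  # Poisson mean per MS/MS scan
    # chromatography (minutes)
    neutral_rt: float = 17.0
    sialylated_rt_offset: float = 2.0
    peak_sigma: float = 0.15
    rt_start: float = 14.0
    rt_end: float = 22.0
    cycle_time: float = 2.0 / 60.0  # one MS1 + all windows per cycle
    # DIA scheme: MS1 + two consecutive 600 Da windows over 600-1800 Th
    dia_windows: Tuple[Tuple[float, float], ...] = ((600.0, 1200.0), (1200.0, 1800.0))
    # MS/MS energy mode
    energy: str = "stepped"  # low | high | stepped
    # DDA
    scans_per_glycoform: int = 5
    include_backbone_ions: bool = False

    def __post_init__(self):
        if self.sialylated_rt_offset <= 0:
            raise ValueError("sialylated RT offset must be positive")
        if self.energy not in ("low", "high", "stepped"):
            raise ValueError(f"unknown energy mode {self.energy!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    panel: pd.DataFrame  # glycan, proportion, apex_rt, metadata columns
    scan_truth: Dict[str, Tuple[str, str]] = field(default_factory=dict)  # scan -> (peptide, glycan)
    feature_content: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Glycoform panels and populations

def _classify(g: GlycanComposition) -> Dict[str, float]:
    """Composition-level metadata used by the intensity model and truth."""
    sia = g["NeuAc"] + g["NeuGc"]
    high_man = g["HexNAc"] == 2 and g["Fuc"] == 0 and sia == 0 and g["Hex"] > 3
    n_gal = 0 if high_man else min(max(g["Hex"] - 3, 0), max(g["HexNAc"] - 2, 0))
    n_man_exposed = g["Hex"] - 3 if high_man else 0
    return {
        "high_mannose": high_man,
        "n_gal": n_gal,
        "n_sia": sia,
        "n_fuc": g["Fuc"],
        "n_man_exposed": n_man_exposed,
    }


def default_igg_panel(n: int = 30) -> List[GlycanComposition]:
    """A deterministic panel of rule-valid IgG-like N-glycan compositions.

    High-mannose Man4-Man9 plus complex-type bi/tri-antennary forms
    with 0-1 core fucose and 0-2 sialic acids, ordered small to large.
    """
    rules = BiosynthesisRules()
    comps = []
    for hexose in range(4, 10):  # high-mannose
        comps.append(GlycanComposition(HexNAc=2, Hex=hexose))
    for hexnac in (3, 4, 5):
        for hexose in range(3, 3 + (hexnac - 2) + 1):
            for fuc in (0, 1):
                max_sia = max(0, hexnac - 2) if hexose > 3 else 0
                for sia in range(0, min(max_sia, 2) + 1):
                    comps.append(
                        GlycanComposition(HexNAc=hexnac, Hex=hexose, Fuc=fuc, NeuAc=sia)
                    )
    valid = [c for c in comps if rules.validate(c)[0]]
    uniq = sorted(set(valid), key=lambda c: (c.total, format_composition(c)))
    return uniq[:n]


CONDITION_WEIGHTS = {
    # preference scores per composition metadata; higher = more abundant
    "ivig": lambda m: 2.0 * m["n_gal"] + 1.5 * m["n_sia"] + 1.0 * m["n_fuc"] - 2.0 * m["high_mannose"],
    "ava": lambda m: 1.5 * m["n_fuc"] - 1.0 * m["n_gal"] - 3.0 * m["n_sia"] + 1.0 * (m["high_mannose"] and m["n_man_exposed"] <= 2),
    "fut-ko": lambda m: -10.0 * m["n_fuc"] + 1.0 * m["n_gal"],
    "gal-ko": lambda m: -10.0 * m["n_gal"] - 10.0 * m["n_sia"] + 1.0 * m["n_fuc"],
    "st-ki": lambda m: 3.0 * m["n_sia"] + 1.0 * m["n_gal"],
    "man-high": lambda m: 3.0 * float(m["high_mannose"]) + 0.5 * m["n_man_exposed"],
    "wt": lambda m: 1.0 * m["n_gal"] + 0.5 * m["n_fuc"],
    "uniform": lambda m: 0.0,
}


def sample_log_series_counts(
    alpha: float, n: int, rng: np.random.Generator, max_species: Optional[int] = None
) -> np.ndarray:
    """Draw a log-series community of expected size N.

    Fisher's model: S = alpha ln(1 + N/alpha) species whose abundances
    are iid log-series draws with x = N/(N+alpha), so the expected
    total count is N.  (Stopping-rule samplers that accumulate species
    until the running total reaches N size-bias the last species and
    overestimate alpha on re-fitting; the fixed-S construction is
    unbiased.)
    """
    if alpha <= 0 or n <= 0:
        raise ValueError("alpha and N must be positive")
    x = n / (n + alpha)
    s = max(1, int(round(alpha * math.log1p(n / alpha))))
    if max_species is not None:
        s = min(s, max_species)
    return np.asarray(_stats.logser.rvs(x, size=s, random_state=rng), dtype=int)


def sample_population(
    config: SimulationConfig,
    panel: Optional[Sequence[GlycanComposition]] = None,
    condition: str = "wt",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Log-series-skewed abundances over a rule-valid glycoform panel.

    One log-series count is drawn per panel member; the largest counts
    are assigned to the compositions most preferred under the condition
    weighting (emulating, e.g., a galactosyltransferase knockout by
    down-ranking galactosylated forms).  Returns a panel table with
    proportions, apex retention times and composition metadata.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    panel = list(panel) if panel is not None else default_igg_panel()
    if not panel:
        raise ValueError("panel must be non-empty")
    if condition not in CONDITION_WEIGHTS:
        raise ValueError(f"unknown condition {condition!r}")
    x = config.population_size / (config.population_size + config.fisher_alpha)
    counts = np.sort(_stats.logser.rvs(x, size=len(panel), random_state=rng))[::-1]
    meta = [_classify(c) for c in panel]
    pref = np.array(
        [CONDITION_WEIGHTS[condition](m) for m in meta], dtype=float
    ) + rng.normal(0, 0.25, len(panel))
    order = np.argsort(-pref, kind="stable")
    proportions = np.empty(len(panel), dtype=float)
    proportions[order] = counts / counts.sum()
    rows = []
    for comp, m, p in zip(panel, meta, proportions):
        apex = config.neutral_rt + (config.sialylated_rt_offset if m["n_sia"] > 0 else 0.0)
        rows.append(
            {
                "glycan": format_composition(comp),
                "proportion": float(p),
                "apex_rt": apex,
                **m,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["condition"] = condition
    return df


def feature_content(panel: pd.DataFrame) -> Dict[str, float]:
    """Abundance-weighted true monosaccharide content of a population."""
    p = panel["proportion"].to_numpy()
    return {
        "fucosylation": float((p * panel["n_fuc"]).sum()),
        "galactosylation": float((p * panel["n_gal"]).sum()),
        "sialylation": float((p * panel["n_sia"]).sum()),
        "high-mannose": float((p * panel["n_man_exposed"]).sum()),
    }


# ---------------------------------------------------------------------------
# Fragment intensity model

_ENERGY_WEIGHTS = {
    # (oxonium, neutral-loss Y, Y1)
    "low": (0.30, 1.00, 0.50),
    "high": (1.00, 0.35, 1.50),
    "stepped": (0.65, 0.675, 1.00),
}


def theoretical_fragments(
    gp: GlycopeptideIon,
    energy: str = "stepped",
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free theoretical MS/MS peak list for one glycopeptide.

    Oxonium weights scale linearly with residue counts, with terminal-
    exposure factors steering hexose signal toward high-mannose forms
    and the 366.14 series toward galactosylated antennae.  Y ions decay
    exponentially with the number of residues lost; Y1 carries its own
    energy-dependent weight.  Three precursor isotopes are included.
    """
    ox_w, y_w, y1_w = _ENERGY_WEIGHTS[energy]
    g = gp.glycan
    m = _classify(g)
    peaks: List[Tuple[float, float]] = []

    def ox(comp: GlycanComposition, weight: float, wl: int = 0):
        if weight > 0 and comp.total and g.contains(comp):
            peaks.append((oxonium_mz(comp, wl, table), 100.0 * ox_w * weight))

    hexnac1 = GlycanComposition(HexNAc=1)
    hex1 = GlycanComposition(Hex=1)
    ox(hexnac1, 1.0 * g["HexNAc"])
    ox(hexnac1, 0.3 * g["HexNAc"], wl=1)
    hex_weight = 0.10 * g["Hex"] + 1.0 * m["n_man_exposed"]
    ox(hex1, hex_weight)
    ox(hex1, 0.4 * hex_weight, wl=1)
    # 366.14 series: terminal Gal-GlcNAc antennae dominate; the core
    # Man-GlcNAc contributes a weak constant term (one core per glycan)
    ox(GlycanComposition(Hex=1, HexNAc=1), 1.0 * m["n_gal"] + 0.15)
    ox(GlycanComposition(NeuAc=1), 1.5 * g["NeuAc"])
    ox(GlycanComposition(NeuAc=1), 0.5 * g["NeuAc"], wl=1)
    ox(GlycanComposition(NeuGc=1), 1.5 * g["NeuGc"])
    ox(GlycanComposition(NeuAc=1, Hex=1, HexNAc=1), 0.8 * g["NeuAc"])
    if g["HexNAc"] >= 1:
        for y in y_ion_ladder(gp, charges=(1,), policy="lattice", table=table):
            w = y1_w if y.is_y1 else y_w * math.exp(-0.5 * y.n_lost)
            peaks.append((y.mz_by_charge[1], 100.0 * w))
    prec_mz = gp.mz(table)
    for k, iso_w in enumerate((1.0, 0.6, 0.25)):
        peaks.append((prec_mz + k * ISOTOPE_SPACING / gp.charge, 40.0 * iso_w))
    peaks.sort()
    merged: List[Tuple[float, float]] = []
    for mz, inten in peaks:
        if merged and abs(merged[-1][0] - mz) < 1e-6:
            merged[-1] = (merged[-1][0], merged[-1][1] + inten)
        else:
            merged.append((mz, inten))
    mz_arr = np.array([p[0] for p in merged])
    int_arr = np.array([p[1] for p in merged])
    return mz_arr, int_arr


def simulate_msms(
    gp: GlycopeptideIon,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    scan_id: str = "scan",
    retention_time: float = 0.0,
    scale: float = 1.0,
    energy: Optional[str] = None,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> Spectrum:
    """One noisy MS/MS spectrum of a glycopeptide.

    With the noise model disabled (jitter 0, CV 0, no noise peaks) the
    peak m/z values equal the theoretical fragment masses exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mz, inten = theoretical_fragments(gp, energy or config.energy, table)
    inten = inten * scale
    if config.mz_jitter_sd > 0:
        mz = mz + rng.normal(0, config.mz_jitter_sd, mz.size)
    if config.intensity_cv > 0:
        inten = inten * np.exp(rng.normal(0, config.intensity_cv, inten.size))
    n_noise = rng.poisson(config.noise_peaks) if config.noise_peaks > 0 else 0
    if n_noise:
        noise_mz = rng.uniform(120.0, min(1800.0, gp.mz(table) + 50.0), n_noise)
        noise_int = inten.max() * rng.uniform(0.002, 0.03, n_noise) if inten.size else rng.uniform(1, 5, n_noise)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=gp.mz(table) + (rng.normal(0, config.mz_jitter_sd) if config.mz_jitter_sd > 0 else 0.0),
        precursor_charge=gp.charge,
        retention_time=retention_time,
        mz=mz,
        intensity=np.maximum(inten, 0.0),
    )


# ---------------------------------------------------------------------------
# Runs

def _panel_ions(
    panel: pd.DataFrame, config: SimulationConfig, table: MonosaccharideTable
) -> List[Tuple[GlycopeptideIon, float, float]]:
    """(ion, proportion, apex_rt) for every backbone x panel row."""
    out = []
    n_pep = len(config.peptides)
    for pep in config.peptides:
        for _, row in panel.iterrows():
            ion = GlycopeptideIon(pep, parse_composition(row["glycan"], table), charge=config.charge)
            out.append((ion, float(row["proportion"]) / n_pep, float(row["apex_rt"])))
    return out


def _elution(t: float, apex: float, sigma: float) -> float:
    return math.exp(-0.5 * ((t - apex) / sigma) ** 2)


def simulate_dda_run(
    panel: pd.DataFrame,
    config: SimulationConfig,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> Tuple[Run, GroundTruth]:
    """DDA emulation: replicate triggered MS/MS scans per glycoform.

    Each glycopeptide receives ``scans_per_glycoform`` MS/MS scans at
    times spread across its elution peak (narrow ~3 Da isolation),
    mimicking repeated data-dependent triggering of an abundant
    precursor.  MS1 survey scans cover the gradient for completeness.
    """
    rng = np.random.default_rng(config.seed)
    ions = _panel_ions(panel, config, table)
    truth = GroundTruth(panel=panel.copy(), feature_content=feature_content(panel))
    spectra: List[Spectrum] = []
    scan_no = 0
    for ion, prop, apex in ions:
        offsets = np.linspace(-config.peak_sigma, config.peak_sigma, config.scans_per_glycoform)
        for off in offsets:
            t = apex + off + rng.normal(0, 0.02)
            scale = max(prop, 1e-4) * _elution(t, apex, config.peak_sigma) * 1e4
            sid = f"dda.{scan_no}"
            s = simulate_msms(ion, config, rng, scan_id=sid, retention_time=t, scale=scale, table=table)
            s.isolation_window = (s.precursor_mz - 1.5, s.precursor_mz + 1.5)
            spectra.append(s)
            truth.scan_truth[sid] = (ion.peptide, format_composition(ion.glycan))
            scan_no += 1
    # MS1 survey scans
    t = config.rt_start
    while t <= config.rt_end:
        mz_list, int_list = [], []
        for ion, prop, apex in ions:
            e = _elution(t, apex, config.peak_sigma)
            if e < 1e-4:
                continue
            m0 = ion.mz(table)
            for k, w in enumerate((1.0, 0.6, 0.25)):
                mz_list.append(m0 + k * ISOTOPE_SPACING / ion.charge)
                int_list.append(prop * e * w * 1e5)
        spectra.append(
            Spectrum(
                scan_id=f"dda.ms1.{round(t * 600)}",
                precursor_mz=0.0,
                ms_level=1,
                retention_time=t,
                mz=np.array(mz_list),
                intensity=np.array(int_list),
            )
        )
        t += config.cycle_time * 5
    spectra.sort(key=lambda s: (s.retention_time, s.scan_id))
    return Run(spectra, mode="DDA"), truth


def simulate_dia_run(
    panel: pd.DataFrame,
    config: SimulationConfig,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> Tuple[Run, GroundTruth]:
    """Wide-window DIA cycles: MS1 + one MS/MS scan per 600 Da window.

    Every MS2 scan contains the summed fragment patterns of all
    co-isolated, co-eluting glycoforms whose precursor m/z falls in the
    window — the GlycoPOP-MS acquisition geometry.
    """
    rng = np.random.default_rng(config.seed + 1)
    ions = _panel_ions(panel, config, table)
    truth = GroundTruth(panel=panel.copy(), feature_content=feature_content(panel))
    theo = [
        (ion, prop, apex, theoretical_fragments(ion, config.energy, table))
        for ion, prop, apex in ions
    ]
    spectra: List[Spectrum] = []
    t = config.rt_start
    cycle = 0
    while t <= config.rt_end:
        mz_list, int_list = [], []
        for ion, prop, apex, _ in theo:
            e = _elution(t, apex, config.peak_sigma)
            if e < 1e-4:
                continue
            m0 = ion.mz(table)
            for k, w in enumerate((1.0, 0.6, 0.25)):
                mz_list.append(m0 + k * ISOTOPE_SPACING / ion.charge)
                int_list.append(prop * e * w * 1e5)
        spectra.append(
            Spectrum(
                scan_id=f"dia.c{cycle}.ms1",
                precursor_mz=0.0,
                ms_level=1,
                retention_time=t,
                mz=np.array(mz_list),
                intensity=np.array(int_list),
            )
        )
        for w_i, (lo, hi) in enumerate(config.dia_windows):
            mz_parts, int_parts = [], []
            for ion, prop, apex, (fmz, fint) in theo:
                m0 = ion.mz(table)
                if not (lo <= m0 < hi):
                    continue
                e = _elution(t, apex, config.peak_sigma)
                if e < 1e-4:
                    continue
                scale = prop * e * 1e4
                mz_parts.append(fmz)
                int_parts.append(fint * scale)
            if mz_parts:
                mz_arr = np.concatenate(mz_parts)
                int_arr = np.concatenate(int_parts)
            else:
                mz_arr, int_arr = np.array([]), np.array([])
            if config.mz_jitter_sd > 0 and mz_arr.size:
                mz_arr = mz_arr + rng.normal(0, config.mz_jitter_sd, mz_arr.size)
            if config.intensity_cv > 0 and int_arr.size:
                int_arr = int_arr * np.exp(rng.normal(0, config.intensity_cv, int_arr.size))
            spectra.append(
                Spectrum(
                    scan_id=f"dia.c{cycle}.w{w_i}",
                    precursor_mz=0.5 * (lo + hi),
                    ms_level=2,
                    retention_time=t + (w_i + 1) * config.cycle_time / (len(config.dia_windows) + 1),
                    isolation_window=(lo, hi),
                    mz=mz_arr,
                    intensity=int_arr,
                )
            )
        t += config.cycle_time
        cycle += 1
    return Run(spectra, mode="DIA", dia_windows=config.dia_windows), truth


TRUNCATED_PLAIN = GlycanComposition(HexNAc=1)
TRUNCATED_FUC = GlycanComposition(HexNAc=1, Fuc=1)


def apply_endos_truncation(
    panel: pd.DataFrame, fraction: float, hemoconcentration: float = 1.0
) -> pd.DataFrame:
    """Move ``fraction`` of each intact glycoform onto its EndoS product.

    The chitobiose core is cleaved, leaving HexNAc(1) — with the core
    fucose retained iff the parent was core-fucosylated.  Total
    abundance per backbone is conserved up to the hemoconcentration
    scale factor.  The returned panel keeps ``proportion`` as absolute
    abundance (it may no longer sum to 1 when hemoconcentration != 1).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("truncation fraction must lie in [0, 1]")
    out: Dict[str, Dict] = {}

    def add(comp_str: str, amount: float, meta: Dict, apex: float):
        if comp_str not in out:
            out[comp_str] = {"glycan": comp_str, "proportion": 0.0, "apex_rt": apex, **meta}
        out[comp_str]["proportion"] += amount

    for _, row in panel.iterrows():
        comp = parse_composition(row["glycan"])
        amount = float(row["proportion"]) * hemoconcentration
        if comp in (TRUNCATED_PLAIN, TRUNCATED_FUC):
            add(row["glycan"], amount, _classify(comp), float(row["apex_rt"]))
            continue
        intact = amount * (1.0 - fraction)
        cleaved = amount * fraction
        if intact > 0:
            add(row["glycan"], intact, _classify(comp), float(row["apex_rt"]))
        if cleaved > 0:
            product = TRUNCATED_FUC if comp["Fuc"] >= 1 else TRUNCATED_PLAIN
            add(
                format_composition(product),
                cleaved,
                _classify(product),
                float(row["apex_rt"]) - 1.0,  # truncated forms elute earlier
            )
    df = pd.DataFrame(list(out.values()))
    df.attrs["truncation_fraction"] = fraction
    return df


def simulate_endos_timecourse(
    panel: pd.DataFrame,
    timepoints: Sequence[float],
    fractions: Sequence[float],
    config: SimulationConfig,
    hemoconcentration: Optional[Sequence[float]] = None,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> Dict[float, Tuple[Run, GroundTruth]]:
    """DIA runs over an infection time course of rising truncation.

    ``fractions`` must be non-decreasing (glycan loss is cumulative);
    at each timepoint the configured fraction of every intact glycoform
    is converted to its HexNAc(1) ± Fuc product before a DIA run is
    simulated.
    """
    if len(timepoints) != len(fractions):
        raise ValueError("timepoints and fractions must align")
    if any(b < a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("truncation fractions must be non-decreasing over time")
    hemo = list(hemoconcentration) if hemoconcentration is not None else [1.0] * len(timepoints)
    out = {}
    for i, (tp, frac) in enumerate(zip(timepoints, fractions)):
        tp_panel = apply_endos_truncation(panel, frac, hemo[i])
        cfg = replace(config, seed=config.seed + 100 + i)
        run, truth = simulate_dia_run(tp_panel, cfg, table)
        out[tp] = (run, truth)
    return out
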