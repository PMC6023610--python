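"""Synthetic dataset generator for the TALE occupancy pipeline.

Builds a self-contained toy study — genome FASTA, two-stage peak sets,
histone-mark bedGraph tracks, TSS annotation, expression/DE tables and
qPCR Ct tables — whose statistical structure matches what the analysis
stages assume about the real system:

* two-stage peak dynamics: ~60% of early (blastula-stage) peaks remain
  occupied late (segmentation stage), and 58% of late-only peaks fall
  within 40 kb of an early peak;
* stage-dependent motif usage: DECA-rich early windows (75%) vs
  HEXA/PBX:HOX-rich late-only windows (44%/24%), with the NF-Y CCAAT box
  planted ~20 bp from DECA sites and the Pbx:Hox site offset ~10 bp from
  the summit;
* chromatin classes: 25% of early peaks carry histone marks (MPADs,
  split into Classes 1-4 by H3K27ac/H3K27me3 level), driving Gaussian
  signal bumps in the emitted tracks;
* expression coupled to class, with a knockdown condition that
  down-regulates Class-4-linked genes.

Background sequence is i.i.d. uniform A/C/G/T.  Every peak's 200 bp summit
window is "scrubbed" of chance motif matches before the intended motifs are
embedded and then re-verified, so the written ground truth is exactly
consistent with regex scanning of the emitted FASTA.
"""

from __future__ import annotations

import bisect
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from talegrn import io as tio
from talegrn.motifs import IUPAC, MotifSpec, default_registry, scan
from talegrn.peaks import Peak, PeakSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}

WINDOW_HALF = 100   # summit windows are 200 bp
SCRUB_HALF = 115    # motif-scrubbed region around each summit
PLACE_HALF = 85     # planted motifs stay this close to the summit
MIN_PEAK_GAP = 600  # guarantees scrub regions never overlap


class SyntheticConfigError(ValueError):
    pass


def _default_motif_rates() -> dict:
    # per-window embedding probabilities by stage; the PBX:HOX "late" entry
    # is the target rate over the full late peak set (retained + late-only)
    return {
        "DECA": {"early": 0.75, "late_only": 0.07},
        "HEXA": {"early": 0.11, "late_only": 0.44},
        "PBX:HOX": {"early": 0.05, "late": 0.24},
    }


def _default_class_proportions() -> dict:
    return {
        "Class1": 0.0625,
        "Class2": 0.0625,
        "Class3": 0.0625,
        "Class4": 0.0625,
        "nonMPAD": 0.75,
    }


def _default_signal_params() -> dict:
    # mark -> class -> mean bump amplitude (arbitrary coverage units)
    return {
        "H3K4me1": {"Class1": 9.0, "Class2": 7.0, "Class3": 5.0, "Class4": 6.0,
                    "nonMPAD": 0.3},
        "H3K27ac": {"Class1": 10.0, "Class2": 5.0, "Class3": 1.5, "Class4": 0.3,
                    "nonMPAD": 0.2},
        "H3K27me3": {"Class1": 0.3, "Class2": 0.3, "Class3": 0.5, "Class4": 6.0,
                     "nonMPAD": 0.1},
        # later timepoint: Class 4 sites gain H3K27ac (repressed-to-active switch)
        "H3K27ac_late": {"Class1": 10.0, "Class2": 5.0, "Class3": 2.5, "Class4": 5.0,
                         "nonMPAD": 0.2},
    }


def _default_expression_params() -> dict:
    return {
        "baseline_tpm": {"Class1": 100.0, "Class2": 50.0, "Class3": 20.0,
                         "Class4": 15.0, "nonMPAD": 20.0, "background": 20.0},
        "gene_log_sd": 0.4,       # per-gene lognormal spread around class baseline
        "replicate_log_sd": 0.15,  # replicate-level measurement noise
        "knockdown_effect": 0.4,   # multiplier on Class4-linked gene means in KD
        "n_replicates": 3,
        "n_background_genes": 300,
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the generator (defaults encode the emulated system)."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 3_000_000
    n_early_peaks: int = 2000
    retention_rate: float = 0.60
    n_late_only_peaks: int = 2000
    frac_late_only_within_40kb: float = 0.58
    motif_rates: dict = field(default_factory=_default_motif_rates)
    nfy_deca_spacing_mean: float = 20.0
    nfy_deca_spacing_sd: float = 4.0
    hox_offset_mean: float = 10.0
    hox_offset_sd: float = 3.0
    class_proportions: dict = field(default_factory=_default_class_proportions)
    signal_params: dict = field(default_factory=_default_signal_params)
    expression_params: dict = field(default_factory=_default_expression_params)
    amp_log_sd: float = 0.15
    bump_sigma: float = 200.0
    noise_sd: float = 0.3
    peak_width: int = 400
    window: int = 200
    weak_peak_fraction: float = 0.10  # early calls below the FE>=10 cutoff
    write_tracks: bool = True

    # internal geometry (fractions of chromosome length)
    margin: int = 5000
    early_zone_frac: float = 0.45

    def validate(self) -> None:
        def frac(name: str) -> None:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {v}")

        for name in ("retention_rate", "frac_late_only_within_40kb",
                     "weak_peak_fraction", "early_zone_frac"):
            frac(name)
        for name in ("n_chroms", "chrom_length", "n_early_peaks", "n_late_only_peaks"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise SyntheticConfigError(f"{name} must be a positive integer, got {v}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"class_proportions must sum to 1, got {total}")
        for motif, rates in self.motif_rates.items():
            for stage, r in rates.items():
                if not (0.0 <= r <= 1.0):
                    raise SyntheticConfigError(
                        f"motif_rates[{motif}][{stage}] must be in [0, 1], got {r}")
        zone = self.early_zone_frac * self.chrom_length - self.margin
        if self.n_early_peaks * MIN_PEAK_GAP > self.n_chroms * zone:
            raise SyntheticConfigError(
                "n_early_peaks too large for the early zone; increase "
                "chrom_length or n_chroms")
        far_len = self.chrom_length - self.margin - (
            int(self.early_zone_frac * self.chrom_length) + 45_000)
        n_far = int(self.n_late_only_peaks * (1 - self.frac_late_only_within_40kb))
        if far_len <= 0 or n_far * 400 > self.n_chroms * far_len:
            raise SyntheticConfigError(
                "n_late_only_peaks too large for the distal zone; increase "
                "chrom_length or n_chroms")

    def chrom_names(self) -> list[str]:
        return [f"chrS{i + 1}" for i in range(self.n_chroms)]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _instantiate(rng: np.random.Generator, consensus: str, strand: str) -> np.ndarray:
    """Concrete uint8 base codes for an IUPAC consensus on the given strand."""
    bases = [IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in consensus.upper()]
    seq = "".join(bases)
    if strand == "-":
        seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return np.array([_CODE[ord(b)] for b in seq], dtype=np.uint8)


def embed_motif(
    sequence: str, motif_consensus: str, position: int, strand: str,
    seed: int | None = None, rng: np.random.Generator | None = None,
) -> str:
    """Embed a concrete instantiation of an IUPAC consensus into a sequence.

    Degenerate codes are resolved by a seeded random choice among their
    options; on the '-' strand the instantiated motif is reverse
    complemented before insertion.  All other bases are unchanged.
    """
    if position < 0 or position + len(motif_consensus) > len(sequence):
        raise ValueError(
            f"motif does not fit at position {position} in a sequence of "
            f"length {len(sequence)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    inst = _instantiate(rng, motif_consensus, strand)
    text = "".join("ACGT"[c] for c in inst)
    return sequence[:position] + text + sequence[position + len(text):]


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


class _WindowPlanner:
    """Plans and writes one peak's scrubbed, motif-embedded summit region."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator,
                 registry: dict[str, MotifSpec]):
        self.cfg = cfg
        self.rng = rng
        self.deca = registry["DECA"]
        self.hexa = registry["HEXA"]
        self.hox = registry["PBX:HOX"]
        self.nfy = registry["NF-Y"]

    def plan(self, want_deca: bool, want_hexa: bool, want_hox: bool) -> dict:
        """Choose motif placements (start offsets relative to the summit)."""
        rng = self.rng
        occupied: list[tuple[int, int]] = []
        placements: list[tuple[str, int, str]] = []
        want_nfy = False
        nfy_spacing = np.nan

        def reserve(start: int, length: int) -> bool:
            if start < -PLACE_HALF or start + length > PLACE_HALF:
                return False
            if any(start + length > a and start < b for a, b in occupied):
                return False
            occupied.append((start, start + length))
            return True

        if want_deca:
            reserve(-5, 10)
            placements.append((self.deca.consensus, -5, "+-"[rng.integers(0, 2)]))
            # NF-Y box a short, configurable distance from the DECA center
            for _ in range(30):
                d = int(np.clip(round(rng.normal(
                    self.cfg.nfy_deca_spacing_mean, self.cfg.nfy_deca_spacing_sd)),
                    12, 60))
                side = 1 if rng.integers(0, 2) else -1
                start = side * d - 3 + int(rng.integers(0, 2))
                if reserve(start, 5):
                    placements.append((self.nfy.consensus, start,
                                       "+-"[rng.integers(0, 2)]))
                    want_nfy, nfy_spacing = True, float(d)
                    break
        elif want_hexa:
            reserve(-3, 6)
            placements.append((self.hexa.consensus, -3, "+-"[rng.integers(0, 2)]))
        if want_hox:
            placed = False
            for _ in range(30):
                o = int(round(rng.normal(self.cfg.hox_offset_mean,
                                         self.cfg.hox_offset_sd)))
                side = 1 if rng.integers(0, 2) else -1
                start = side * o - 4
                if reserve(start, 8):
                    placements.append((self.hox.consensus, start,
                                       "+-"[rng.integers(0, 2)]))
                    placed = True
                    break
            want_hox = placed
        return {
            "placements": placements,
            "deca": want_deca,
            "hexa": want_hexa and not want_deca,
            "hox": want_hox,
            "nfy": want_nfy,
            "nfy_spacing": nfy_spacing,
        }

    def verify(self, window: str, plan: dict) -> bool:
        deca_raw = bool(scan(window, self.deca))
        if deca_raw != plan["deca"]:
            return False
        if not plan["deca"] and bool(scan(window, self.hexa)) != plan["hexa"]:
            return False
        if bool(scan(window, self.hox)) != plan["hox"]:
            return False
        if bool(scan(window, self.nfy)) != plan["nfy"]:
            return False
        return True

    def write(self, chrom_codes: np.ndarray, summit: int, plan: dict) -> None:
        """Rewrite the scrub region until the central window verifies."""
        rng = self.rng
        for _ in range(300):
            region = rng.integers(0, 4, 2 * SCRUB_HALF, dtype=np.uint8)
            for consensus, start_rel, strand in plan["placements"]:
                inst = _instantiate(rng, consensus, strand)
                s = start_rel + SCRUB_HALF
                region[s: s + len(inst)] = inst
            window = _codes_to_str(
                region[SCRUB_HALF - WINDOW_HALF: SCRUB_HALF + WINDOW_HALF])
            if self.verify(window, plan):
                chrom_codes[summit - SCRUB_HALF: summit + SCRUB_HALF] = region
                return
        raise RuntimeError("could not realize motif plan (pathological config)")


def _layout_early_summits(cfg: SyntheticConfig, rng: np.random.Generator
                          ) -> list[tuple[str, int]]:
    names = cfg.chrom_names()
    zone_end = int(cfg.early_zone_frac * cfg.chrom_length)
    per_chrom = np.full(cfg.n_chroms, cfg.n_early_peaks // cfg.n_chroms)
    per_chrom[: cfg.n_early_peaks % cfg.n_chroms] += 1
    out = []
    for chrom, n_c in zip(names, per_chrom):
        if n_c == 0:
            continue
        spacing = (zone_end - cfg.margin) / n_c
        jitter_max = max(0.0, spacing / 2.0 - MIN_PEAK_GAP / 2.0)
        centers = cfg.margin + spacing * (np.arange(n_c) + 0.5)
        jitter = rng.uniform(-jitter_max, jitter_max, n_c)
        for pos in np.sort(centers + jitter).astype(int):
            out.append((chrom, int(pos)))
    return out


def _layout_late_only(cfg: SyntheticConfig, rng: np.random.Generator,
                      early: list[tuple[str, int]]) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Place late-only summits: a configured fraction near an early peak."""
    names = cfg.chrom_names()
    zone_end = int(cfg.early_zone_frac * cfg.chrom_length)
    far_start = zone_end + 45_000
    early_by_chrom: dict[str, list[int]] = {c: [] for c in names}
    for chrom, s in early:
        early_by_chrom[chrom].append(s)
    placed: dict[str, list[int]] = {c: [] for c in names}

    def clear(chrom: str, pos: int, min_early: int, min_late: int) -> bool:
        for arr, lim in ((early_by_chrom[chrom], min_early), (placed[chrom], min_late)):
            i = bisect.bisect_left(arr, pos)
            for j in (i - 1, i):
                if 0 <= j < len(arr) and abs(arr[j] - pos) < lim:
                    return False
        return True

    near_mask = rng.random(cfg.n_late_only_peaks) < cfg.frac_late_only_within_40kb
    out: list[tuple[str, int]] = []
    for near in near_mask:
        for _ in range(1000):
            if near:
                chrom, anchor = early[int(rng.integers(0, len(early)))]
                d = int(rng.integers(300, 39_701))
                pos = anchor + (d if rng.integers(0, 2) else -d)
                if pos < cfg.margin or pos > cfg.chrom_length - cfg.margin:
                    continue
            else:
                chrom = names[int(rng.integers(0, cfg.n_chroms))]
                pos = int(rng.integers(far_start, cfg.chrom_length - cfg.margin))
            if clear(chrom, pos, 260, 250):
                bisect.insort(placed[chrom], pos)
                out.append((chrom, pos))
                break
        else:
            raise RuntimeError("could not place a late-only peak; genome too dense")
    return out, near_mask


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Generate the full synthetic dataset and write it under ``out_dir``.

    Returns a manifest dict: per-file sha256/size plus a ``summary`` block
    with realized counts (retained peaks, planted motif counts, etc.).
    The same config always produces byte-identical files.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    registry = default_registry()
    planner = _WindowPlanner(config, rng, registry)
    rates = config.motif_rates
    names = config.chrom_names()
    L = config.chrom_length

    # --- genome background -------------------------------------------------
    chroms = {c: rng.integers(0, 4, L, dtype=np.uint8) for c in names}

    # --- peak geometry -----------------------------------------------------
    early_pos = _layout_early_summits(config, rng)
    n_early = len(early_pos)
    retained = rng.random(n_early) < config.retention_rate
    late_only_pos, near_mask = _layout_late_only(config, rng, early_pos)
    n_lo = len(late_only_pos)
    n_ret = int(retained.sum())

    # PBX:HOX is specified as a rate over the full late set; solve for the
    # late-only embedding rate that achieves it given the retained windows
    hox_rates = rates.get("PBX:HOX", {})
    hox_early = hox_rates.get("early", 0.0)
    if "late_only" in hox_rates:
        hox_lo = hox_rates["late_only"]
    else:
        target = hox_rates.get("late", 0.0)
        hox_lo = float(np.clip(
            (target * (n_ret + n_lo) - n_ret * hox_early) / max(n_lo, 1), 0.0, 1.0))

    # --- class labels ------------------------------------------------------
    class_names = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in class_names])
    classes = [class_names[i] for i in rng.choice(len(class_names), n_early, p=probs)]

    # --- plant motifs ------------------------------------------------------
    truth_rows = []
    half_w = config.peak_width // 2
    deca_e, hexa_e = rates["DECA"]["early"], rates["HEXA"]["early"]
    deca_lo, hexa_lo = rates["DECA"]["late_only"], rates["HEXA"]["late_only"]

    def hexa_embed_rate(hexa_rate: float, deca_rate: float) -> float:
        # HEXA is measured with DECA exclusion, so the embedding rate among
        # DECA-free windows must be inflated to hit the marginal target
        if deca_rate >= 1.0:
            return 0.0
        return min(1.0, hexa_rate / (1.0 - deca_rate))

    early_plans = []
    for i, (chrom, summit) in enumerate(early_pos):
        want_deca = rng.random() < deca_e
        want_hexa = (not want_deca) and rng.random() < hexa_embed_rate(hexa_e, deca_e)
        want_hox = rng.random() < hox_early
        plan = planner.plan(want_deca, want_hexa, want_hox)
        planner.write(chroms[chrom], summit, plan)
        early_plans.append(plan)

    lo_plans = []
    for chrom, summit in late_only_pos:
        want_deca = rng.random() < deca_lo
        want_hexa = (not want_deca) and rng.random() < hexa_embed_rate(hexa_lo, deca_lo)
        want_hox = rng.random() < hox_lo
        plan = planner.plan(want_deca, want_hexa, want_hox)
        planner.write(chroms[chrom], summit, plan)
        lo_plans.append(plan)

    # --- peak objects and files --------------------------------------------
    def make_fe() -> float:
        if rng.random() < config.weak_peak_fraction:
            return float(np.round(rng.uniform(2.0, 10.0 - 1e-6), 3))
        return float(np.round(10.0 + rng.gamma(2.0, 10.0), 3))

    genome_map = {c: L for c in names}
    early_peaks, late_peaks = [], []
    for i, (chrom, summit) in enumerate(early_pos):
        pid = f"E{i + 1:05d}"
        early_peaks.append(Peak(chrom, summit - half_w, summit + half_w, summit,
                                make_fe(), pid))
        if retained[i]:
            # a retained site keeps its summit: occupancy persists in place
            late_peaks.append(Peak(chrom, summit - half_w, summit + half_w, summit,
                                   make_fe(), f"L{pid}"))
    for j, (chrom, summit) in enumerate(late_only_pos):
        late_peaks.append(Peak(chrom, summit - half_w, summit + half_w, summit,
                               make_fe(), f"LO{j + 1:05d}"))
    early_set = PeakSet("early", early_peaks, genome=genome_map)
    late_set = PeakSet("late", late_peaks, genome=genome_map)

    # --- truth table (flags recomputed from the written sequence) ----------
    def window_flags(chrom: str, summit: int) -> dict:
        win = _codes_to_str(chroms[chrom][summit - WINDOW_HALF: summit + WINDOW_HALF])
        deca = bool(scan(win, registry["DECA"]))
        return {
            "deca": deca,
            "hexa": (not deca) and bool(scan(win, registry["HEXA"])),
            "pbx_hox": bool(scan(win, registry["PBX:HOX"])),
            "nfy": bool(scan(win, registry["NF-Y"])),
        }

    for i, (chrom, summit) in enumerate(early_pos):
        row = {"peak_id": f"E{i + 1:05d}", "stage": "early", "chrom": chrom,
               "summit": summit, "class_label": classes[i],
               "origin": "", "nfy_spacing": early_plans[i]["nfy_spacing"]}
        row.update(window_flags(chrom, summit))
        truth_rows.append(row)
        if retained[i]:
            row = {"peak_id": f"LE{i + 1:05d}", "stage": "late", "chrom": chrom,
                   "summit": summit, "class_label": classes[i],
                   "origin": f"E{i + 1:05d}",
                   "nfy_spacing": early_plans[i]["nfy_spacing"]}
            row.update(window_flags(chrom, summit))
            truth_rows.append(row)
    for j, (chrom, summit) in enumerate(late_only_pos):
        row = {"peak_id": f"LO{j + 1:05d}", "stage": "late_only", "chrom": chrom,
               "summit": summit, "class_label": "", "origin": "",
               "nfy_spacing": lo_plans[j]["nfy_spacing"]}
        row.update(window_flags(chrom, summit))
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    # --- signal tracks -----------------------------------------------------
    track_files: dict[str, Path] = {}
    if config.write_tracks:
        bin_size = 25
        nbins = -(-L // bin_size)
        sigma = config.bump_sigma
        reach = 1200
        for mark, amps in config.signal_params.items():
            grids = {c: np.zeros(nbins) for c in names}
            touched = {c: np.zeros(nbins, dtype=bool) for c in names}
            for i, (chrom, summit) in enumerate(early_pos):
                amp = amps[classes[i]] * float(
                    np.exp(rng.normal(0.0, config.amp_log_sd)))
                b0 = max(0, (summit - reach) // bin_size)
                b1 = min(nbins, (summit + reach) // bin_size + 1)
                centers = (np.arange(b0, b1) + 0.5) * bin_size
                grids[chrom][b0:b1] += amp * np.exp(
                    -((centers - summit) ** 2) / (2 * sigma**2))
                touched[chrom][b0:b1] = True
            runs = {}
            for chrom in names:
                mask = touched[chrom]
                vals = grids[chrom]
                vals[mask] = np.clip(
                    vals[mask] + rng.normal(0.0, config.noise_sd, int(mask.sum())),
                    0.0, None)
                idx = np.nonzero(vals > 1e-4)[0]
                starts = idx * bin_size
                ends = np.minimum((idx + 1) * bin_size, L)
                runs[chrom] = (starts, ends, np.round(vals[idx], 4))
            fname = mark.lower().replace(":", "_") + ".bedGraph"
            path = out / fname
            tio.write_bedgraph(runs, path)
            track_files[mark] = path

    # --- genes, expression, DE ---------------------------------------------
    xp = config.expression_params
    gene_rows = []
    for i, (chrom, summit) in enumerate(early_pos):
        sign = 1 if rng.integers(0, 2) else -1
        tss = int(np.clip(summit + sign * rng.integers(1000, 25_001),
                          config.margin, L - config.margin))
        gene_rows.append({"gene_id": f"g{i + 1:05d}", "chrom": chrom, "tss": tss,
                          "strand": "+-"[rng.integers(0, 2)],
                          "linked_peak": f"E{i + 1:05d}", "class_label": classes[i]})
    zone_end = int(config.early_zone_frac * L)
    for b in range(xp["n_background_genes"]):
        chrom = names[int(rng.integers(0, config.n_chroms))]
        tss = int(rng.integers(zone_end + 40_000, L - config.margin))
        gene_rows.append({"gene_id": f"bg{b + 1:04d}", "chrom": chrom, "tss": tss,
                          "strand": "+-"[rng.integers(0, 2)],
                          "linked_peak": "", "class_label": "background"})
    genes = pd.DataFrame(gene_rows)

    n_rep = xp["n_replicates"]
    base = genes["class_label"].map(xp["baseline_tpm"]).to_numpy(dtype=float)
    gene_mean = base * np.exp(rng.normal(0.0, xp["gene_log_sd"], len(genes)))
    is_kd_target = (genes["class_label"] == "Class4").to_numpy()
    kd_mean = gene_mean * np.where(is_kd_target, xp["knockdown_effect"], 1.0)
    expr = {"gene_id": genes["gene_id"]}
    for r in range(n_rep):
        expr[f"ctrl_rep{r + 1}"] = np.round(
            gene_mean * np.exp(rng.normal(0.0, xp["replicate_log_sd"], len(genes))), 3)
    for r in range(n_rep):
        expr[f"kd_rep{r + 1}"] = np.round(
            kd_mean * np.exp(rng.normal(0.0, xp["replicate_log_sd"], len(genes))), 3)
    expression = pd.DataFrame(expr)

    effect = xp["knockdown_effect"]
    null_fc = np.exp(rng.normal(0.0, 0.05, len(genes)))
    fc_mag = np.where(is_kd_target, 1.0 / effect, np.maximum(null_fc, 1.0 / null_fc))
    de = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "fold_change": np.round(fc_mag, 4),
        "padj": np.round(np.where(is_kd_target, 1e-6, rng.uniform(0.2, 1.0, len(genes))), 6),
        "direction": np.where(is_kd_target, "down",
                              np.where(null_fc >= 1.0, "up", "down")),
    })

    # --- qPCR Ct table (H3K27ac ChIP at Class4-linked sites) ---------------
    targets = genes.loc[genes["class_label"] == "Class4", "gene_id"].head(8).tolist()
    ct_rows = []
    for t in targets:
        for cond, ratio in (("control", 4.0), ("tale_kd", 4.0 * 0.35)):
            for rep in range(1, 4):
                ct_in = float(rng.normal(20.0, 0.1))
                true_ratio = ratio * float(np.exp(rng.normal(0.0, 0.08)))
                ct_rows.append({
                    "target": t, "condition": cond, "replicate": rep,
                    "ct": round(ct_in - float(np.log2(true_ratio)), 3),
                    "reference_ct": round(ct_in, 3),
                })
    ct_table = pd.DataFrame(ct_rows)

    # --- write everything --------------------------------------------------
    files: dict[str, Path] = {}
    files["genome"] = out / "genome.fa"
    tio.write_fasta({c: _BASES[chroms[c]].tobytes() for c in names}, files["genome"])
    files["peaks_early"] = out / "peaks_early.narrowPeak"
    tio.write_narrowpeak(early_set, files["peaks_early"])
    files["peaks_late"] = out / "peaks_late.narrowPeak"
    tio.write_narrowpeak(late_set, files["peaks_late"])
    files["tss"] = out / "tss.bed"
    tio.write_bed6(
        [(g.chrom, g.tss, g.tss + 1, g.gene_id, 0, g.strand)
         for g in genes.itertuples()],
        files["tss"])
    for mark, path in track_files.items():
        files[f"track_{mark}"] = path
    files["expression"] = out / "expression.tsv"
    expression.to_csv(files["expression"], sep="\t", index=False)
    files["de"] = out / "de.tsv"
    de.to_csv(files["de"], sep="\t", index=False)
    files["ct"] = out / "ct.tsv"
    ct_table.to_csv(files["ct"], sep="\t", index=False)
    files["truth_peaks"] = out / "truth_peaks.tsv"
    truth.to_csv(files["truth_peaks"], sep="\t", index=False)
    files["truth_genes"] = out / "truth_genes.tsv"
    genes.assign(true_de=is_kd_target).to_csv(files["truth_genes"], sep="\t", index=False)
    files["config"] = out / "config.yaml"
    config.to_yaml(files["config"])

    manifest = tio.write_manifest(files, out / "manifest.json")
    manifest["summary"] = {
        "n_early": n_early,
        "n_retained": n_ret,
        "n_late_only": n_lo,
        "n_late": len(late_peaks),
        "n_late_only_near": int(near_mask.sum()),
        "pbx_hox_late_only_rate": hox_lo,
        "n_genes": len(genes),
    }
    return manifest
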