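"""Synthetic PSM, phosphopeptide and splicing tables with known ground truth.

The generator emulates a single-batch 16-plex isobaric-label experiment:
two cell lines (WT and a doxycycline-inducible DUX4 myoblast line) crossed
with treatment/timepoint conditions, 2-4 replicates each.  Measurement
noise is Gaussian on the log2 scale (log-normal reporter intensities, the
standard TMT error model); per-sample loading offsets are constant log2
shifts, exactly the artifact median normalization must remove; peptides of
one protein differ by constant ionization offsets, exactly the artifact
median polish absorbs into row effects.

Planted effects are rank-tiered: up-regulated features are drawn from the
top of the base-abundance distribution and down-regulated features from
the bottom.  Median normalization is only a correct model when the median
feature is non-differential; tiered planting enforces that identifiability
assumption exactly, so with zero noise the full pipeline recovers planted
fold changes to machine precision rather than up to an O(1/n) median
shift.  Phosphopeptide effects decompose as parent-protein effect plus an
independent site-level effect, mirroring the decoupling of transcript/
protein abundance from phosphorylation signaling that motivates the
phospho-to-protein adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS, PsmTable, SampleDesign
from .exceptions import ValidationError

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: TMTpro 16-plex reporter channel labels
TMTPRO16_CHANNELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
]


def default_design() -> SampleDesign:
    """The study layout: one TMTpro 16-plex.

    iDUX4 myoblasts in four conditions (DMSO 14 h reference; dox 2, 6 and
    14 h) with three biological replicates each, plus WT myoblasts treated
    with DMSO or dox for 14 h with two replicates each: 16 channels.
    """
    rows = []
    for cond_i, (cell, trt, tp, reps, ref) in enumerate([
        ("iDUX4", "DMSO", 14, 3, True),
        ("iDUX4", "dox", 2, 3, False),
        ("iDUX4", "dox", 6, 3, False),
        ("iDUX4", "dox", 14, 3, False),
        ("WT", "DMSO", 14, 2, False),
        ("WT", "dox", 14, 2, False),
    ]):
        for r in range(1, reps + 1):
            rows.append((f"S{len(rows) + 1:02d}", cell, trt, tp, r, ref))
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "cell_line", "treatment", "timepoint_h",
                 "replicate", "is_reference"],
    )
    table.insert(1, "channel", TMTPRO16_CHANNELS[: len(table)])
    return SampleDesign(table[DESIGN_COLUMNS])


@dataclass
class EffectSpec:
    """Parameters of the synthetic experiment.

    Counts are per simulated dataset; fold changes are log2; noise terms
    are standard deviations on the log2 scale.  ``loading_offsets_log2``
    may be None (drawn N(0, 0.3) per sample), a scalar SD, or an explicit
    per-sample sequence.  Defaults reflect a desk-scale version of the
    modeled study: a few percent of proteins changed, a larger independent
    set of phospho-site effects, ~0.3 log2 units of reporter noise.
    """

    n_proteins: int = 300
    peptides_per_protein: tuple[int, int] = (2, 5)
    psms_per_peptide: tuple[int, int] = (1, 3)
    frac_proteins_changed: float = 0.05
    protein_log2fc: float = 1.0
    n_phosphopeptides: int = 500
    frac_phospho_changed: float = 0.065
    phospho_log2fc: float = 1.5
    noise_sd_log2: float = 0.3
    ionization_spread_sd_log2: float = 1.0
    loading_offsets_log2: object = None
    base_log2_range: tuple[float, float] = (18.0, 26.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_proteins_changed", "frac_phospho_changed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("n_proteins", "n_phosphopeptides"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("peptides_per_protein", "psms_per_peptide"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name} must be a range with 1 <= lo <= hi")
        for name in ("noise_sd_log2", "ionization_spread_sd_log2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted effects, one row per feature and non-reference condition.

    ``protein`` columns: protein_accession, condition, true_log2fc;
    ``phospho`` columns: peptide_id, protein_accession, condition,
    site_log2fc, total_log2fc (= parent + site).  ``protein_base`` maps
    accession to its base log2 abundance.
    """

    protein: pd.DataFrame
    protein_base: dict[str, float]
    phospho: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["peptide_id", "protein_accession", "condition",
                     "site_log2fc", "total_log2fc"]
        )
    )

    def true_protein_lfc(self, accession: str, condition: str) -> float:
        sub = self.protein[
            (self.protein["protein_accession"] == accession)
            & (self.protein["condition"] == condition)
        ]
        return float(sub["true_log2fc"].iloc[0]) if len(sub) else 0.0


def _loading_offsets(spec: EffectSpec, design: SampleDesign,
                     rng: np.random.Generator) -> np.ndarray:
    n = len(design.sample_ids)
    lo = spec.loading_offsets_log2
    if lo is None:
        return rng.normal(0.0, 0.3, n)
    if np.isscalar(lo):
        return rng.normal(0.0, float(lo), n)
    arr = np.asarray(lo, dtype=float)
    if arr.shape != (n,):
        raise ValidationError(
            f"loading_offsets_log2 must have one value per sample ({n})"
        )
    return arr


def _affected_conditions(design: SampleDesign) -> list[str]:
    """Non-reference conditions of the reference's cell line.

    These carry the planted effects; the other cell line acts as the
    untreated control arm (true fold change zero everywhere).
    """
    ref = design.reference_condition
    ref_cell = design.table.loc[
        design.table["condition"] == ref, "cell_line"
    ].iloc[0]
    return [
        c
        for c in design.non_reference_conditions()
        if design.table.loc[design.table["condition"] == c, "cell_line"].iloc[0]
        == ref_cell
    ]


def _random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.integers(8, 21, n)
    return ["".join(rng.choice(_AMINO_ACIDS, L)) + "K" for L in lengths]


def _tiered_signs(order_desc: np.ndarray, n_up: int, n_down: int) -> np.ndarray:
    """Return per-feature signs: +1 for the top ``n_up`` of a descending
    abundance order, -1 for the bottom ``n_down``, 0 elsewhere."""
    signs = np.zeros(len(order_desc))
    if n_up:
        signs[order_desc[:n_up]] = 1.0
    if n_down:
        signs[order_desc[len(order_desc) - n_down:]] = -1.0
    return signs


def simulate_psm_table(
    design: SampleDesign, spec: EffectSpec
) -> tuple[PsmTable, GroundTruth]:
    """Simulate a protein-level PSM reporter-intensity table.

    Each PSM intensity is 2^(protein base + peptide ionization offset +
    planted log2FC of the sample's condition + per-sample loading offset +
    N(0, noise_sd)).  Effects are planted rank-tiered (see module notes).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    bases = rng.uniform(*spec.base_log2_range, n)
    n_changed = int(round(spec.frac_proteins_changed * n))
    n_down = n_changed // 2
    n_up = n_changed - n_down
    signs = _tiered_signs(np.argsort(-bases), n_up, n_down)

    affected = _affected_conditions(design)
    conditions = [design.condition_of(s) for s in design.sample_ids]
    loading = _loading_offsets(spec, design, rng)

    accessions = np.array([f"P{i + 1:05d}" for i in range(n)])
    pep_counts = rng.integers(
        spec.peptides_per_protein[0], spec.peptides_per_protein[1] + 1, n
    )
    prot_of_pep = np.repeat(np.arange(n), pep_counts)
    n_pep = len(prot_of_pep)
    pep_offsets = rng.normal(0.0, spec.ionization_spread_sd_log2, n_pep)
    sequences = _random_peptides(rng, n_pep)
    charges = rng.integers(2, 4, n_pep)
    psm_counts = rng.integers(
        spec.psms_per_peptide[0], spec.psms_per_peptide[1] + 1, n_pep
    )
    pep_of_psm = np.repeat(np.arange(n_pep), psm_counts)
    n_psm = len(pep_of_psm)

    lfc_per_cond = {
        c: signs * spec.protein_log2fc if c in affected else np.zeros(n)
        for c in dict.fromkeys(conditions)
    }
    log2 = np.empty((n_psm, len(conditions)))
    prot_of_psm = prot_of_pep[pep_of_psm]
    for j, (cond, load) in enumerate(zip(conditions, loading)):
        log2[:, j] = (
            bases[prot_of_psm]
            + pep_offsets[pep_of_psm]
            + lfc_per_cond[cond][prot_of_psm]
            + load
        )
    if spec.noise_sd_log2 > 0:
        log2 += rng.normal(0.0, spec.noise_sd_log2, log2.shape)

    table = pd.DataFrame(
        {
            "peptide_sequence": np.array(sequences)[pep_of_psm],
            "modifications": "",
            "charge": charges[pep_of_psm],
            "protein_accession": accessions[prot_of_psm],
        }
    )
    table[design.sample_ids] = 2.0 ** log2

    truth_rows = [
        {
            "protein_accession": accessions[i],
            "condition": c,
            "true_log2fc": float(lfc_per_cond[c][i]),
        }
        for c in design.non_reference_conditions()
        for i in range(n)
    ]
    truth = GroundTruth(
        protein=pd.DataFrame(truth_rows),
        protein_base=dict(zip(accessions, bases)),
    )
    return PsmTable(table, design.sample_ids), truth


def simulate_phospho_psm_table(
    design: SampleDesign, spec: EffectSpec, truth: GroundTruth
) -> tuple[PsmTable, GroundTruth]:
    """Simulate a phosphopeptide PSM table consistent with ``truth``.

    Each phosphopeptide inherits its parent protein's planted abundance
    effect; a fraction additionally carries an independent site-level
    effect (planted only on peptides of unchanged parents, rank-tiered by
    parent abundance).  The returned truth adds the phospho records: the
    true total log2FC is parent + site, so the expected adjusted value
    after phospho-to-protein normalization is the site effect alone.
    """
    if truth.protein.empty and spec.n_phosphopeptides:
        raise ValidationError("phospho simulation needs protein ground truth")
    rng = np.random.default_rng([spec.seed, 7])
    n = spec.n_phosphopeptides
    accs = np.array(sorted(truth.protein_base))
    bases = np.array([truth.protein_base[a] for a in accs])
    known = set(truth.protein["protein_accession"])
    unknown = set(accs) - known
    if unknown:
        raise ValidationError(
            f"phosphopeptide parent pool references unknown protein(s): "
            f"{sorted(unknown)[:5]}"
        )
    parents = rng.integers(0, len(accs), n)

    affected = _affected_conditions(design)
    non_ref = design.non_reference_conditions()
    parent_lfc = {
        c: truth.protein.set_index(["protein_accession", "condition"])[
            "true_log2fc"
        ].reindex(pd.MultiIndex.from_arrays([accs[parents], [c] * n])).to_numpy()
        for c in non_ref
    }

    n_site = int(round(spec.frac_phospho_changed * n))
    n_site_down = n_site // 2
    n_site_up = n_site - n_site_down
    parent_changed = np.zeros(n, dtype=bool)
    for c in affected:
        parent_changed |= parent_lfc[c] != 0
    candidates = np.where(~parent_changed)[0]
    if len(candidates) < n_site:
        raise ValidationError(
            "not enough phosphopeptides with unchanged parents to plant "
            f"{n_site} site effects"
        )
    cand_desc = candidates[np.argsort(-bases[parents[candidates]])]
    site_signs = np.zeros(n)
    site_signs[cand_desc[:n_site_up]] = 1.0
    if n_site_down:
        site_signs[cand_desc[len(cand_desc) - n_site_down:]] = -1.0

    site_lfc = {
        c: site_signs * spec.phospho_log2fc if c in affected else np.zeros(n)
        for c in non_ref
    }

    sequences = _random_peptides(rng, n)
    site_pos = rng.integers(1, 15, n)
    site_res = rng.choice(np.array(["S", "T", "Y"]), n, p=[0.8, 0.15, 0.05])
    mods = [f"Phospho[{r}{p}]" for r, p in zip(site_res, site_pos)]
    charges = rng.integers(2, 4, n)
    site_offsets = rng.normal(0.0, spec.ionization_spread_sd_log2, n)
    psm_counts = rng.integers(
        spec.psms_per_peptide[0], spec.psms_per_peptide[1] + 1, n
    )
    pep_of_psm = np.repeat(np.arange(n), psm_counts)
    n_psm = len(pep_of_psm)

    conditions = [design.condition_of(s) for s in design.sample_ids]
    loading = _loading_offsets(spec, design, rng)
    ref = design.reference_condition
    total_lfc = {
        c: parent_lfc[c] + site_lfc[c] for c in non_ref
    }
    total_lfc[ref] = np.zeros(n)
    for c in dict.fromkeys(conditions):
        total_lfc.setdefault(c, np.zeros(n))

    log2 = np.empty((n_psm, len(conditions)))
    for j, (cond, load) in enumerate(zip(conditions, loading)):
        log2[:, j] = (
            bases[parents[pep_of_psm]]
            + site_offsets[pep_of_psm]
            + total_lfc[cond][pep_of_psm]
            + load
        )
    if spec.noise_sd_log2 > 0:
        log2 += rng.normal(0.0, spec.noise_sd_log2, log2.shape)

    table = pd.DataFrame(
        {
            "peptide_sequence": np.array(sequences)[pep_of_psm],
            "modifications": np.array(mods)[pep_of_psm],
            "charge": charges[pep_of_psm],
            "protein_accession": accs[parents[pep_of_psm]],
        }
    )
    table[design.sample_ids] = 2.0 ** log2

    peptide_ids = [
        f"{s}/{m}/{z}" for s, m, z in zip(sequences, mods, charges)
    ]
    phospho_rows = [
        {
            "peptide_id": peptide_ids[i],
            "protein_accession": accs[parents[i]],
            "condition": c,
            "site_log2fc": float(site_lfc[c][i]),
            "total_log2fc": float(total_lfc[c][i]),
        }
        for c in non_ref
        for i in range(n)
    ]
    out_truth = GroundTruth(
        protein=truth.protein,
        protein_base=truth.protein_base,
        phospho=pd.DataFrame(phospho_rows),
    )
    return PsmTable(table, design.sample_ids), out_truth


def simulate_lsv_table(
    n_genes: int,
    frac_significant: float,
    seed: int,
    events_per_lsv: tuple[int, int] = (2, 4),
) -> tuple[pd.DataFrame, dict]:
    """Simulate a VOILA-style event table with planted significant genes.

    Exactly ``round(frac_significant * n_genes)`` genes receive one event
    with posterior probability above 0.95 and |E[dPSI]| >= 0.2; all other
    events sit safely below the threshold.  Returns the event table and a
    truth dict with the planted gene set and directional tallies.
    """
    if not 0 <= frac_significant <= 1:
        raise ValidationError("frac_significant must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sig = int(round(frac_significant * n_genes))
    sig_genes = rng.choice(n_genes, n_sig, replace=False)
    sig_mask = np.zeros(n_genes, dtype=bool)
    sig_mask[sig_genes] = True

    rows = []
    tallies = {
        "exon_skip_up": 0, "exon_skip_down": 0,
        "intron_retention_up": 0, "intron_retention_down": 0,
    }
    for g in range(n_genes):
        gene = f"GENE{g + 1:05d}"
        lsv = f"{gene}:s:{rng.integers(1000, 9999)}-{rng.integers(1000, 9999)}"
        n_ev = int(rng.integers(events_per_lsv[0], events_per_lsv[1] + 1))
        sig_slot = int(rng.integers(0, n_ev)) if sig_mask[g] else -1
        for e in range(n_ev):
            kind = str(rng.choice(["junction", "intron_retention"], p=[0.7, 0.3]))
            skip = bool(rng.random() < 0.5) if kind == "junction" else False
            if e == sig_slot:
                p = float(rng.uniform(0.96, 0.999))
                dpsi = float(rng.uniform(0.2, 0.6) * rng.choice([-1.0, 1.0]))
                direction = "up" if dpsi > 0 else "down"
                if kind == "intron_retention":
                    tallies[f"intron_retention_{direction}"] += 1
                elif skip:
                    tallies[f"exon_skip_{direction}"] += 1
            else:
                p = float(rng.uniform(0.0, 0.9))
                dpsi = float(rng.uniform(-0.15, 0.15))
            rows.append((gene, lsv, kind, int(skip), dpsi, p))
    events = pd.DataFrame(
        rows,
        columns=["gene_id", "lsv_id", "event_kind", "exon_skip",
                 "e_dpsi", "p_ge_threshold"],
    )
    events["exon_skip"] = events["exon_skip"].astype(bool)
    truth = {
        "n_significant_genes": n_sig,
        "significant_genes": sorted(f"GENE{g + 1:05d}" for g in sig_genes),
        **tallies,
    }
    return events, truth


def write_truth(truth: GroundTruth, protein_path, phospho_path=None) -> None:
    truth.protein.to_csv(protein_path, sep="\t", index=False, float_format="%.10g")
    if phospho_path is not None:
        truth.phospho.to_csv(phospho_path, sep="\t", index=False, float_format="%.10g")
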