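"""MS1 peak matching and MS2 diagnostic-fragment site localization.

MS1: observed peaks are matched to deduplicated candidate compositions
within a ppm tolerance (default 5 ppm, the identification tolerance).

MS2: a modification is localized to a moiety (core / side_chain /
adb_residue) by scoring every legal assignment hypothesis against the
observed product ions.  Each scaffold ships a table of acylium-family
diagnostic fragments; a rule assigned to a moiety covered by a fragment
shifts that fragment by the rule's delta mass, while precursor-derived
neutral-loss fragments shift with every modification.  Modifications on
the ADB residue — which no acylium fragment covers — are localized by
elimination: core and side-chain fragments stay unshifted while the
precursor mass moves.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .formula import (
    Composition,
    IonMode,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)
from .rules import CandidateGroup, RuleSet

__all__ = [
    "Ms1Peak",
    "Ms2Spectrum",
    "ScaffoldFragment",
    "NeutralLoss",
    "MatchResult",
    "AnnotationRecord",
    "PeakListError",
    "load_peaklist",
    "load_ms2",
    "default_fragments",
    "match_ms1",
    "predict_fragments",
    "localize_moieties",
    "annotate_dataset",
    "records_to_frame",
]


class PeakListError(ValueError):
    """Raised for malformed peak-list / MS2 CSV input."""


@dataclass(frozen=True)
class Ms1Peak:
    id: str
    mz: float
    intensity: float = 1.0
    rt_min: float | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise PeakListError(f"peak {self.id}: m/z must be positive")
        if self.intensity < 0:
            raise PeakListError(f"peak {self.id}: negative intensity")


@dataclass(frozen=True)
class Ms2Spectrum:
    precursor_id: str
    ions: tuple[tuple[float, float], ...]  # (m/z, intensity)

    def __post_init__(self):
        for mz, _ in self.ions:
            if mz <= 0:
                raise PeakListError(
                    f"spectrum {self.precursor_id}: non-positive ion m/z"
                )


@dataclass(frozen=True)
class ScaffoldFragment:
    label: str
    cation: Composition
    covers: frozenset[str]

    @property
    def base_mz(self) -> float:
        return ion_mz(self.cation, IonMode.CATION)


@dataclass(frozen=True)
class NeutralLoss:
    label: str
    composition: Composition

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.composition)


@dataclass(frozen=True)
class MatchResult:
    peak_id: str
    group: CandidateGroup
    ppm: float
    tolerance: float


@dataclass
class AnnotationRecord:
    peak_id: str
    observed_mz: float
    composition: Composition
    theoretical_mz: float
    ppm: float
    applied: tuple[str, ...]
    moiety_assignment: tuple[tuple[str, str], ...]  # (rule_id, moiety)
    supporting_ions: list[tuple[float, str, float]]  # (obs m/z, label, ppm)
    unexplained_ions: list[float]
    status: str  # localized | ambiguous | undetermined
    alternatives: list[tuple[tuple[str, str], ...]] = field(default_factory=list)

    @property
    def ambiguity_flag(self) -> bool:
        return self.status != "localized"


# -- input ------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PeakListError(f"{what}: missing column(s) {missing}")


def load_peaklist(path) -> list[Ms1Peak]:
    """Read an MS1 peak-list CSV with columns id, mz, intensity[, rt_min]."""
    df = pd.read_csv(path)
    _require_columns(df, ["id", "mz", "intensity"], "peak list")
    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mz = float(row.mz)
            inten = float(row.intensity)
        except (TypeError, ValueError):
            raise PeakListError(f"peak list row {i}: non-numeric mz/intensity") from None
        rt = getattr(row, "rt_min", None)
        rt = None if rt is None or pd.isna(rt) else float(rt)
        try:
            peaks.append(Ms1Peak(id=str(row.id), mz=mz, intensity=inten, rt_min=rt))
        except PeakListError as exc:
            raise PeakListError(f"peak list row {i}: {exc}") from None
    return peaks


def load_ms2(path) -> list[Ms2Spectrum]:
    """Read an MS2 CSV (precursor_id, mz, intensity) into spectra."""
    df = pd.read_csv(path)
    _require_columns(df, ["precursor_id", "mz", "intensity"], "MS2 table")
    spectra: dict[str, list[tuple[float, float]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            mz = float(row.mz)
            inten = float(row.intensity)
        except (TypeError, ValueError):
            raise PeakListError(f"MS2 row {i}: non-numeric mz/intensity") from None
        if mz <= 0:
            raise PeakListError(f"MS2 row {i}: non-positive m/z")
        spectra.setdefault(str(row.precursor_id), []).append((mz, inten))
    return [Ms2Spectrum(pid, tuple(ions)) for pid, ions in spectra.items()]


# -- fragment tables --------------------------------------------------------


def _load_fragment_config() -> dict:
    ref = resources.files("phasemet.data").joinpath("fragments.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_fragments(
    scaffold: str,
) -> tuple[list[ScaffoldFragment], list[NeutralLoss]]:
    """Packaged diagnostic fragment table and neutral losses for a scaffold."""
    cfg = _load_fragment_config()
    if scaffold not in cfg:
        raise KeyError(f"no fragment table for scaffold {scaffold!r}")
    frags = [
        ScaffoldFragment(
            label=f["label"],
            cation=parse_formula(f["cation"]),
            covers=frozenset(f["covers"]),
        )
        for f in cfg[scaffold]["fragments"]
    ]
    losses = [
        NeutralLoss(label=l["label"], composition=parse_formula(l["formula"]))
        for l in cfg["neutral_losses"]
    ]
    return frags, losses


# -- MS1 matching -----------------------------------------------------------


def match_ms1(
    peaks: list[Ms1Peak],
    groups: list[CandidateGroup],
    tolerance_ppm: float = 5.0,
) -> list[MatchResult]:
    """All (peak, candidate-group) pairs within the ppm tolerance."""
    out = []
    for peak in peaks:
        for g in groups:
            err = ppm_error(peak.mz, g.theoretical_mz)
            if abs(err) <= tolerance_ppm:
                out.append(
                    MatchResult(
                        peak_id=peak.id, group=g, ppm=err, tolerance=tolerance_ppm
                    )
                )
    return out


# -- MS2 localization -------------------------------------------------------


def predict_fragments(
    candidate_composition: Composition,
    hypothesis: tuple[tuple[str, str], ...],
    ruleset: RuleSet,
    fragments: list[ScaffoldFragment],
    losses: list[NeutralLoss],
) -> list[tuple[str, float]]:
    """Predicted product-ion m/z values under one site-assignment hypothesis.

    ``hypothesis`` maps each applied rule instance to a moiety.  Acylium
    fragments accumulate the deltas of rules assigned to covered moieties
    (fragments driven to a negative element count are dropped — e.g. a
    fluorine rule on an already defluorinated fragment).  Neutral-loss
    fragments derive from the full candidate and shift with every rule.
    """
    for rule_id, moiety in hypothesis:
        rule = ruleset.get(rule_id)
        if moiety not in rule.allowed_moieties:
            raise ValueError(
                f"rule {rule_id} may not be assigned to moiety {moiety!r}"
            )
    out: list[tuple[str, float]] = []
    for frag in fragments:
        comp = frag.cation
        ok = True
        for rule_id, moiety in hypothesis:
            if moiety in frag.covers:
                rule = ruleset.get(rule_id)
                if not comp.can_add(rule.delta):
                    ok = False
                    break
                comp = comp.add(rule.delta)
        if ok:
            out.append((frag.label, ion_mz(comp, IonMode.CATION)))
    precursor_mz = ion_mz(candidate_composition, IonMode.PROTONATED)
    protonated = candidate_composition.add({"H": 1})
    for loss in losses:
        neg = {e: -n for e, n in loss.composition.counts}
        if protonated.can_add(neg):
            out.append((loss.label, precursor_mz - loss.mass))
    return out


def _hypotheses(applied: tuple[str, ...], ruleset: RuleSet):
    """Unique moiety assignments for a rule multiset (order-insensitive)."""
    option_lists = [sorted(ruleset.get(rid).allowed_moieties) for rid in applied]
    seen = set()
    for choice in itertools.product(*option_lists):
        hyp = tuple(sorted(zip(applied, choice)))
        if hyp not in seen:
            seen.add(hyp)
            yield hyp


def localize_moieties(
    group: CandidateGroup,
    ms2: Ms2Spectrum | None,
    ruleset: RuleSet,
    fragments: list[ScaffoldFragment],
    losses: list[NeutralLoss],
    ms2_tolerance_ppm: float = 10.0,
    peak_id: str | None = None,
    observed_mz: float | None = None,
) -> AnnotationRecord:
    """Pick the site-assignment hypothesis best supported by the MS2 ions.

    Scores every legal hypothesis of every provenance multiset of the
    candidate group by the number of observed ions matching a predicted
    fragment within tolerance; ties are reported, never silently broken.
    """
    pid = peak_id or (ms2.precursor_id if ms2 is not None else "")
    obs = observed_mz if observed_mz is not None else group.theoretical_mz
    base = dict(
        peak_id=pid,
        observed_mz=obs,
        composition=group.composition,
        theoretical_mz=group.theoretical_mz,
        ppm=ppm_error(obs, group.theoretical_mz),
    )
    if ms2 is None or not ms2.ions:
        return AnnotationRecord(
            **base,
            applied=group.provenance[0] if group.provenance else (),
            moiety_assignment=(),
            supporting_ions=[],
            unexplained_ions=[],
            status="undetermined",
        )

    scored: list[tuple[int, tuple, tuple, list, list]] = []
    for applied in group.provenance:
        for hyp in _hypotheses(applied, ruleset):
            predicted = predict_fragments(
                group.composition, hyp, ruleset, fragments, losses
            )
            supporting: list[tuple[float, str, float]] = []
            unexplained: list[float] = []
            for obs_mz, _inten in ms2.ions:
                best: tuple[float, str, float] | None = None
                for label, pred_mz in predicted:
                    err = ppm_error(obs_mz, pred_mz)
                    if abs(err) <= ms2_tolerance_ppm and (
                        best is None or abs(err) < abs(best[2])
                    ):
                        best = (obs_mz, label, err)
                if best is not None:
                    supporting.append(best)
                else:
                    unexplained.append(obs_mz)
            scored.append((len(supporting), applied, hyp, supporting, unexplained))

    best_score = max(s[0] for s in scored)
    winners = sorted(
        (s for s in scored if s[0] == best_score), key=lambda s: (s[1], s[2])
    )
    score, applied, hyp, supporting, unexplained = winners[0]
    status = "localized" if len(winners) == 1 else "ambiguous"
    if score == 0:
        status = "undetermined"
    return AnnotationRecord(
        **base,
        applied=applied,
        moiety_assignment=hyp,
        supporting_ions=supporting,
        unexplained_ions=unexplained,
        status=status,
        alternatives=[w[2] for w in winners[1:]],
    )


# -- end-to-end -------------------------------------------------------------


def _natural_key(s: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]


def annotate_dataset(
    peaks: list[Ms1Peak],
    spectra: list[Ms2Spectrum],
    groups: list[CandidateGroup],
    ruleset: RuleSet,
    fragments: list[ScaffoldFragment],
    losses: list[NeutralLoss],
    ms1_tolerance_ppm: float = 5.0,
    ms2_tolerance_ppm: float = 10.0,
) -> tuple[list[AnnotationRecord], dict]:
    """Match every peak and localize every match; deterministic output.

    Returns annotation records sorted by (peak id, theoretical m/z) and a
    summary dict with matched/unmatched/ambiguous counts.
    """
    ms2_by_id = {s.precursor_id: s for s in spectra}
    matches = match_ms1(peaks, groups, ms1_tolerance_ppm)
    by_peak: dict[str, list[MatchResult]] = {}
    for m in matches:
        by_peak.setdefault(m.peak_id, []).append(m)
    records: list[AnnotationRecord] = []
    for peak in sorted(peaks, key=lambda p: _natural_key(p.id)):
        for m in sorted(by_peak.get(peak.id, []), key=lambda m: m.group.theoretical_mz):
            rec = localize_moieties(
                m.group,
                ms2_by_id.get(peak.id),
                ruleset,
                fragments,
                losses,
                ms2_tolerance_ppm,
                peak_id=peak.id,
                observed_mz=peak.mz,
            )
            records.append(rec)
    matched_ids = set(by_peak)
    summary = {
        "n_peaks": len(peaks),
        "n_matched_peaks": len(matched_ids),
        "n_unmatched_peaks": len(peaks) - len(matched_ids),
        "unmatched_peak_ids": sorted(
            (p.id for p in peaks if p.id not in matched_ids), key=_natural_key
        ),
        "n_records": len(records),
        "n_ambiguous": sum(r.status == "ambiguous" for r in records),
        "n_undetermined": sum(r.status == "undetermined" for r in records),
        "ms1_tolerance_ppm": ms1_tolerance_ppm,
        "ms2_tolerance_ppm": ms2_tolerance_ppm,
    }
    return records, summary


def records_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records into a table mirroring the reference CSVs."""
    rows = []
    for r in records:
        rows.append(
            {
                "peak_id": r.peak_id,
                "observed_mz": round(r.observed_mz, 4),
                "formula": r.composition.format(),
                "theoretical_mz": round(r.theoretical_mz, 4),
                "ppm": round(r.ppm, 2),
                "reactions": ";".join(f"{rid}:{moi}" for rid, moi in r.moiety_assignment)
                or ";".join(r.applied),
                "status": r.status,
                "supporting_ions": ";".join(
                    f"{mz:.4f}={label}" for mz, label, _ in r.supporting_ions
                ),
                "unexplained_ions": ";".join(f"{mz:.4f}" for mz in r.unexplained_ions),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "observed_mz",
            "formula",
            "theoretical_mz",
            "ppm",
            "reactions",
            "status",
            "supporting_ions",
            "unexplained_ions",
        ],
    )
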