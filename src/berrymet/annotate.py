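"""Ion annotation: co-elution grouping, adduct/isotope role assignment,
neutral-mass inference, library matching and identification-confidence levels.

The workflow mirrors standard untargeted electrospray post-processing:
features that co-elute (within a +/-10 s retention-time window) and whose
per-sample intensities correlate strongly (Pearson r > 0.8) are grouped as
ions of one compound; accurate mass differences inside each group identify
isotopologues, adduct pairs and in-source fragments; the inferred neutral
mass is matched against a compound library; and each feature receives a
Metabolomics Standards Initiative (MSI) confidence level 1/2/2+/3/4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    C13_SPACING,
    DEFAULT_ADDUCTS,
    ELECTRON_MASS,
    Adduct,
    adducts_for,
    default_adduct,
    ppm_error,
)
from .io import parse_fragment_list, sample_columns

RT_WINDOW_S = 10.0
R_MIN = 0.8
MIN_SHARED_SAMPLES = 3
MASS_TOL = 0.005  # Da, for isotope spacing / adduct differences / corroboration
FRAGMENT_TOL = 0.01  # Da, observed m/z vs reference MS2 fragment
PPM_TOL = 5.0
ABS_TOL = 0.015  # Da, library window for masses below the ppm crossover
PPM_CROSSOVER_MASS = 300.0
RT_REF_TOL_MIN = 0.2

MSI_LEVELS = ("1", "2plus", "2", "3", "4")


# ---------------------------------------------------------------------------
# co-elution grouping
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_features(
    peaks: pd.DataFrame,
    sample_ids: list[str] | None = None,
    rt_window_s: float = RT_WINDOW_S,
    r_min: float = R_MIN,
    min_shared: int = MIN_SHARED_SAMPLES,
) -> pd.Series:
    """Single-linkage co-elution clusters over the thresholded correlation graph.

    Two features are linked when their retention times differ by at most
    ``rt_window_s`` seconds and the Pearson correlation of their intensities
    over shared non-missing samples (at least ``min_shared`` of them)
    exceeds ``r_min``.  Returns a Series feature_id -> group_id; group ids
    are assigned in order of the group's earliest-eluting member and are
    independent of the input row order.

    Constant (zero-variance) features are never linked to anything.
    """
    cols = sample_ids if sample_ids is not None else sample_columns(peaks)
    ids = list(peaks["feature_id"])
    rt = peaks["rt_min"].to_numpy(float)
    X = peaks[cols].to_numpy(float)

    order = np.argsort(rt, kind="stable")
    uf = _UnionFind(ids)
    window_min = rt_window_s / 60.0

    for oi in range(len(order)):
        i = order[oi]
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            if rt[j] - rt[i] > window_min + 1e-12:
                break
            xi, xj = X[i], X[j]
            shared = ~(np.isnan(xi) | np.isnan(xj))
            if shared.sum() < min_shared:
                continue
            a, b = xi[shared], xj[shared]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r > r_min:
                uf.union(ids[i], ids[j])

    roots: dict[str, list[str]] = {}
    for fid in ids:
        roots.setdefault(uf.find(fid), []).append(fid)
    # deterministic group numbering by earliest elution then feature id
    rt_of = dict(zip(ids, rt))
    ordered_groups = sorted(
        roots.values(), key=lambda members: (min(rt_of[m] for m in members), sorted(members)[0])
    )
    mapping = {}
    for gid, members in enumerate(ordered_groups):
        for m in members:
            mapping[m] = gid
    return pd.Series(mapping, name="group_id").loc[ids]


# ---------------------------------------------------------------------------
# role assignment and neutral-mass inference
# ---------------------------------------------------------------------------


@dataclass
class SubGroup:
    """One parent ion and the satellites explained from it."""

    base_feature: str
    base_adduct: str
    neutral_mass: float
    roles: dict[str, str]  # member feature_id -> role ('base' for the parent)


@dataclass
class GroupAnnotation:
    """Role assignment for one co-eluting correlation group.

    A correlation group may contain more than one genuinely co-eluting
    compound; annotation therefore proceeds iteratively, peeling off one
    parent ion (plus the satellites its adduct/isotope arithmetic
    explains) at a time.  ``subgroups[0]`` is the primary (best-explaining)
    parent; leftover members that no parent explains keep role
    'unassigned'.
    """

    group_id: int
    subgroups: list[SubGroup]
    unassigned: list[str]
    tie_broken: bool = False

    @property
    def base_feature(self) -> str:
        return self.subgroups[0].base_feature

    @property
    def base_adduct(self) -> str:
        return self.subgroups[0].base_adduct

    @property
    def neutral_mass(self) -> float:
        return self.subgroups[0].neutral_mass

    @property
    def roles(self) -> dict[str, str]:
        out = {}
        for sg in self.subgroups:
            out.update(sg.roles)
        for fid in self.unassigned:
            out[fid] = "unassigned"
        return out


def _monomer_adducts(polarity: str, table) -> list[Adduct]:
    return [a for a in adducts_for(polarity, table) if a.n_mer == 1]


def annotate_roles(
    group: pd.DataFrame,
    polarity: str,
    adduct_table=DEFAULT_ADDUCTS,
    iso_tol: float = MASS_TOL,
    adduct_tol: float = MASS_TOL,
) -> GroupAnnotation:
    """Assign base/isotope/adduct roles within one co-eluting ion group.

    ``group`` needs columns feature_id, mz and one column per sample (used
    only for mean intensities).  Each parent (base) ion is the member from
    which the most other remaining members can be explained by isotope
    spacing, adduct-pair mass differences or dimer arithmetic; ties break
    by highest mean intensity then lowest m/z.  The procedure repeats on
    the unexplained remainder, so several genuinely co-eluting compounds
    in one correlation group each get their own parent.
    """
    cols = sample_columns(group)
    ids = list(group["feature_id"])
    mz = dict(zip(ids, group["mz"].astype(float)))
    mean_int = dict(
        zip(ids, np.nanmean(group[cols].to_numpy(float), axis=1) if cols else np.zeros(len(ids)))
    )
    gid = int(group["group_id"].iloc[0]) if "group_id" in group else -1

    monomers = _monomer_adducts(polarity, adduct_table)
    dimers = [a for a in adducts_for(polarity, adduct_table) if a.n_mer == 2]
    default_label = default_adduct(polarity).label

    def species_priority(adduct: Adduct) -> int:
        if adduct.label == default_label:
            return 0
        if adduct.label == "[M]+":
            return 1
        return 2

    def best_candidate(members: list[str]):
        candidates = []
        for fid in members:
            for sp in monomers:
                neutral = sp.neutral_mass(mz[fid])
                if neutral <= 0:
                    continue
                roles: dict[str, str] = {fid: "base"}
                score = 0
                for other in members:
                    if other == fid:
                        continue
                    delta = mz[other] - mz[fid]
                    assigned = None
                    for k in (1, 2):
                        if abs(delta - k * C13_SPACING) <= iso_tol and mean_int[other] < mean_int[fid]:
                            assigned = "isotope"
                            break
                    if assigned is None:
                        for sp2 in monomers:
                            if sp2.label == sp.label:
                                continue
                            if abs(mz[other] - sp2.mz(neutral)) <= adduct_tol:
                                assigned = f"adduct:{sp2.label}"
                                break
                    if assigned is None:
                        for sp2 in dimers:
                            if abs(mz[other] - sp2.mz(neutral)) <= adduct_tol:
                                assigned = f"adduct:{sp2.label}"
                                break
                    if assigned is not None:
                        roles[other] = assigned
                        score += 1
                candidates.append(
                    (score, -species_priority(sp), mean_int[fid], -mz[fid], fid, sp, roles)
                )
        candidates.sort(key=lambda c: c[:4], reverse=True)
        return candidates

    remaining = list(ids)
    subgroups: list[SubGroup] = []
    tie = False
    while remaining:
        candidates = best_candidate(remaining)
        score, _, _, _, base_fid, base_sp, roles = candidates[0]
        if subgroups and score == 0:
            break  # nothing left that explains anything: leftovers stay unassigned
        if not subgroups:
            # a tie is only informative when some member was actually explained
            tie = (
                len(candidates) > 1
                and score > 0
                and candidates[1][0] == score
                and candidates[1][4] != base_fid
            )
            if tie:
                warnings.warn(
                    f"ambiguous base ion in group {gid}; tie-break by intensity then m/z",
                    stacklevel=2,
                )
        subgroups.append(
            SubGroup(
                base_feature=base_fid,
                base_adduct=base_sp.label,
                neutral_mass=base_sp.neutral_mass(mz[base_fid]),
                roles=roles,
            )
        )
        remaining = [f for f in remaining if f not in roles]
    return GroupAnnotation(group_id=gid, subgroups=subgroups, unassigned=remaining, tie_broken=tie)


# ---------------------------------------------------------------------------
# library matching and MSI levels
# ---------------------------------------------------------------------------


def match_library(
    neutral_mass: float,
    library: pd.DataFrame,
    ppm_tol: float = PPM_TOL,
    abs_tol: float = ABS_TOL,
) -> pd.DataFrame:
    """Library entries whose neutral mass matches the query.

    A hit is within ``ppm_tol`` ppm for masses at or above 300 Da, or
    within ``abs_tol`` Da below that crossover.  Hits are sorted by
    absolute ppm error, ties by name; each carries its signed ppm error.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    lib_mass = library["neutral_mass"].to_numpy(float)
    delta = neutral_mass - lib_mass
    if neutral_mass >= PPM_CROSSOVER_MASS:
        ok = np.abs(delta) <= ppm_tol * lib_mass * 1e-6
    else:
        ok = np.abs(delta) <= abs_tol
    hits = library.loc[ok].copy()
    hits["ppm_error"] = [ppm_error(neutral_mass, m) for m in hits["neutral_mass"]]
    return hits.sort_values(
        by=["ppm_error", "name"], key=lambda s: s.abs() if s.name == "ppm_error" else s
    ).reset_index(drop=True)


def assign_msi_level(evidence: dict[str, bool]) -> str:
    """MSI confidence from evidence flags.

    Flags: mass_match, rt_match, rt_available, ms2_match, ms3_match,
    ms3_available, unique_hit.  Level 1 needs mass, RT and MS2 agreement
    with an authentic standard (plus MS3 when a reference exists); 2+ is
    mass + MS2 without an RT standard; 2 is a unique accurate-mass match;
    3 an ambiguous (isomeric/class-level) mass match; 4 unknown.
    """
    mass = evidence.get("mass_match", False)
    rt = evidence.get("rt_match", False)
    rt_avail = evidence.get("rt_available", False)
    ms2 = evidence.get("ms2_match", False)
    ms3_ok = (not evidence.get("ms3_available", False)) or evidence.get("ms3_match", False)
    unique = evidence.get("unique_hit", False)
    if mass and rt and ms2 and ms3_ok:
        return "1"
    if mass and ms2 and not rt_avail:
        return "2plus"
    if mass and unique:
        return "2"
    if mass:
        return "3"
    return "4"


# ---------------------------------------------------------------------------
# full per-polarity annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationResult:
    table: pd.DataFrame  # one row per feature with roles, masses, hits, levels
    groups: list[GroupAnnotation] = field(default_factory=list)


def annotate_features(
    peaks: pd.DataFrame,
    library: pd.DataFrame,
    polarity: str,
    sample_ids: list[str] | None = None,
    adduct_table=DEFAULT_ADDUCTS,
    rt_window_s: float = RT_WINDOW_S,
    r_min: float = R_MIN,
    ppm_tol: float = PPM_TOL,
    abs_tol: float = ABS_TOL,
    mass_tol: float = MASS_TOL,
) -> AnnotationResult:
    """Group, role-assign, library-match and MSI-level one polarity's table."""
    group_ids = group_features(peaks, sample_ids=sample_ids, rt_window_s=rt_window_s, r_min=r_min)
    peaks = peaks.copy()
    peaks["group_id"] = group_ids.to_numpy()

    rows = []
    group_anns = []
    for gid, sub in peaks.groupby("group_id"):
        ann = annotate_roles(sub, polarity, adduct_table, iso_tol=mass_tol, adduct_tol=mass_tol)
        group_anns.append(ann)
        mz_of = dict(zip(sub["feature_id"], sub["mz"].astype(float)))
        rt_of = dict(zip(sub["feature_id"], sub["rt_min"].astype(float)))
        unclaimed = list(ann.unassigned)

        def _match_with_cation_fallback(neutral: float, base_fid: str, adduct_label: str):
            hits = match_library(neutral, library, ppm_tol, abs_tol)
            # intrinsic-cation fallback: a flavylium M+ misread as [M+H]
            # finds no library entry; retry the [M]+ interpretation
            if len(hits) == 0 and polarity == "positive" and adduct_label == "[M+H]+":
                alt = mz_of[base_fid] + ELECTRON_MASS
                alt_hits = match_library(alt, library, ppm_tol, abs_tol)
                if len(alt_hits):
                    return alt_hits, alt, "[M]+"
            return hits, neutral, adduct_label

        def _record(fid, role, neutral, best, n_hits, msi):
            rows.append(
                {
                    "feature_id": fid,
                    "rt_min": rt_of[fid],
                    "mz": mz_of[fid],
                    "polarity": polarity,
                    "group_id": gid,
                    "role": role,
                    "neutral_mass": neutral,
                    "best_hit_name": best["name"] if best is not None else "",
                    "n_hits": n_hits,
                    "ppm_error": float(best["ppm_error"]) if best is not None else np.nan,
                    "msi_level": msi,
                }
            )

        for sg in ann.subgroups:
            hits, sg.neutral_mass, sg.base_adduct = _match_with_cation_fallback(
                sg.neutral_mass, sg.base_feature, sg.base_adduct
            )
            best = hits.iloc[0] if len(hits) else None
            ref_frags = parse_fragment_list(best["ms2_ref"]) if best is not None else []

            # leftover lower-mass co-members: in-source fragments when they
            # match a reference MS2 fragment of this subgroup's library hit
            ms2_match = False
            for fid in list(unclaimed):
                if ref_frags and any(abs(mz_of[fid] - f) <= FRAGMENT_TOL for f in ref_frags):
                    sg.roles[fid] = "in_source_fragment"
                    unclaimed.remove(fid)
                    ms2_match = True

            rt_available = best is not None and pd.notna(best.get("rt_ref"))
            base_rt = rt_of[sg.base_feature]
            evidence = {
                "mass_match": best is not None,
                "unique_hit": len(hits) == 1,
                "rt_available": rt_available,
                "rt_match": bool(
                    rt_available and abs(base_rt - float(best["rt_ref"])) <= RT_REF_TOL_MIN
                ),
                "ms2_match": ms2_match,
                "ms3_available": best is not None and bool(parse_fragment_list(best["ms3_ref"])),
                "ms3_match": False,
            }
            msi = assign_msi_level(evidence)
            for fid, role in sg.roles.items():
                _record(fid, role, sg.neutral_mass, best, len(hits), msi)

        # members no parent explains: library-match them on their own
        for fid in unclaimed:
            neutral = default_adduct(polarity).neutral_mass(mz_of[fid])
            hits, neutral, _ = _match_with_cation_fallback(neutral, fid, default_adduct(polarity).label)
            best = hits.iloc[0] if len(hits) else None
            evidence = {"mass_match": best is not None, "unique_hit": len(hits) == 1}
            _record(fid, "unassigned", neutral, best, len(hits), assign_msi_level(evidence))
        ann.unassigned = unclaimed
    table = (
        pd.DataFrame(rows)
        .set_index("feature_id")
        .loc[peaks["feature_id"]]
        .reset_index()
    )
    return AnnotationResult(table=table, groups=group_anns)


def collapse_redundancy(annotation: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep one representative ion per group; drop satellites.

    Base ions and unassigned members are retained; isotopes, adducts and
    in-source fragments are removed.  Returns (retained annotation rows,
    removal ledger keyed by reason).
    """
    reasons = {"isotope": 0, "adduct": 0, "in_source_fragment": 0}
    keep = []
    for _, row in annotation.iterrows():
        role = row["role"]
        if role == "isotope":
            reasons["isotope"] += 1
        elif role.startswith("adduct:"):
            reasons["adduct"] += 1
        elif role == "in_source_fragment":
            reasons["in_source_fragment"] += 1
        else:
            keep.append(row["feature_id"])
    retained = annotation[annotation["feature_id"].isin(keep)].reset_index(drop=True)
    assert len(annotation) == len(retained) + sum(reasons.values())
    return retained, reasons


def merge_polarities(
    pos_peaks: pd.DataFrame,
    neg_peaks: pd.DataFrame,
    pos_annotation: pd.DataFrame,
    neg_annotation: pd.DataFrame,
    mass_tol: float = MASS_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack both polarities into one feature x sample matrix.

    Rows from both polarities are retained (intensities are never fused);
    a feature is flagged corroborated when a feature of the other polarity
    infers the same neutral mass within ``mass_tol``.  Sample sets must
    agree between the two tables.
    """
    pos_samples = set(sample_columns(pos_peaks))
    neg_samples = set(sample_columns(neg_peaks))
    if pos_samples != neg_samples:
        asym = sorted(pos_samples ^ neg_samples)
        raise ValueError(f"sample sets differ between polarities: {asym}")

    def _flag(ann: pd.DataFrame, other: pd.DataFrame) -> pd.Series:
        other_masses = np.sort(other["neutral_mass"].to_numpy(float))
        def near(m):
            i = np.searchsorted(other_masses, m)
            for j in (i - 1, i):
                if 0 <= j < len(other_masses) and abs(other_masses[j] - m) <= mass_tol:
                    return True
            return False
        return ann["neutral_mass"].map(near)

    pos_ann = pos_annotation.copy()
    neg_ann = neg_annotation.copy()
    pos_ann["corroborated"] = _flag(pos_ann, neg_ann)
    neg_ann["corroborated"] = _flag(neg_ann, pos_ann)

    cols = ["feature_id", "rt_min", "mz", *sorted(pos_samples)]
    combined = pd.concat([pos_peaks[cols], neg_peaks[cols]], ignore_index=True)
    annotation = pd.concat([pos_ann, neg_ann], ignore_index=True)
    return combined, annotation
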