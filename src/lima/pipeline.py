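"""Applied-analysis front end for harmonized summary statistics.

Accepts one tab-separated association table per trait with the header
``variant_id  effect_allele  other_allele  beta  se  p  n`` (standardized
effects), and produces a :class:`~lima.data.SummaryData` ready for the
estimators. The pipeline assumes pre-clumped, approximately independent
instruments (LD clumping against a reference panel is out of scope); an
optional user-supplied LD matrix enables a simple greedy r^2 filter.

Steps: Steiger filtering of exposure instruments, IVW-based candidate
mediator selection, forward-stepwise correlation pruning, and assembly of
the five summary-statistic blocks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import InvalidParameterError, SummaryData
from .mr import ivw_total_effect

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele",
                    "beta", "se", "p", "n")
GENOME_WIDE_P = 5e-8
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def read_assoc_table(path: str | Path) -> pd.DataFrame:
    """Read and validate one harmonized association table."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise InvalidParameterError(f"{path}: duplicated variant {dup!r}")
    if (df["se"] <= 0).any():
        raise InvalidParameterError(f"{path}: non-positive standard errors")
    return df


def drop_palindromic(table: pd.DataFrame) -> pd.DataFrame:
    """Remove strand-ambiguous (palindromic) SNPs."""
    pairs = list(zip(table["effect_allele"].str.upper(),
                     table["other_allele"].str.upper()))
    keep = [p not in _AMBIGUOUS_PAIRS for p in pairs]
    return table.loc[keep].reset_index(drop=True)


def _aligned(left: pd.DataFrame, right: pd.DataFrame, ids) -> pd.DataFrame:
    """Inner-join two tables on variant id with allele checking.

    Effects in ``right`` are sign-flipped when its effect/other alleles are
    swapped relative to ``left``; any other allele combination is an error.
    """
    merged = left[left["variant_id"].isin(ids)].merge(
        right, on="variant_id", suffixes=("_l", "_r"))
    ea_l = merged["effect_allele_l"].str.upper()
    oa_l = merged["other_allele_l"].str.upper()
    ea_r = merged["effect_allele_r"].str.upper()
    oa_r = merged["other_allele_r"].str.upper()
    same = (ea_l == ea_r) & (oa_l == oa_r)
    swapped = (ea_l == oa_r) & (oa_l == ea_r)
    bad = ~(same | swapped)
    if bad.any():
        v = merged.loc[bad, "variant_id"].iloc[0]
        raise InvalidParameterError(f"allele mismatch for variant {v!r}")
    merged.loc[swapped, "beta_r"] = -merged.loc[swapped, "beta_r"]
    return merged


def steiger_filter(exposure: pd.DataFrame, outcome: pd.DataFrame,
                   candidate_ids) -> list[str]:
    """Drop candidates with a stronger, nominally significant outcome signal.

    A variant is removed when its outcome association is both significant
    (p < 0.05) and stronger (smaller p) than its exposure association — the
    signature of an instrument acting through reverse causation. Returns
    the surviving variant ids in the input order.
    """
    candidate_ids = list(candidate_ids)
    merged = _aligned(exposure, outcome, candidate_ids)
    lookup = merged.set_index("variant_id")
    survivors = []
    for vid in candidate_ids:
        if vid not in lookup.index:
            continue
        row = lookup.loc[vid]
        p_exp, p_out = float(row["p_l"]), float(row["p_r"])
        if p_out < 0.05 and p_out < p_exp:
            continue
        survivors.append(vid)
    return survivors


def _mediator_instruments(mediator: pd.DataFrame, p_instrument: float) -> pd.DataFrame:
    return mediator[mediator["p"] < p_instrument]


def _ivw_pair(exposure_tab: pd.DataFrame, outcome_tab: pd.DataFrame,
              instrument_ids) -> float:
    """IVW MR p-value between two traits over the given instruments."""
    merged = _aligned(exposure_tab, outcome_tab, instrument_ids)
    if merged.empty:
        return 1.0
    res = ivw_total_effect(merged["beta_l"].to_numpy(),
                           merged["beta_r"].to_numpy(),
                           merged["se_r"].to_numpy() ** 2)
    return res.p_value


def select_candidate_mediators(exposure: pd.DataFrame, mediators: dict,
                               outcome: pd.DataFrame, p_em: float = 0.05,
                               p_mo: float = 0.05,
                               p_instrument: float = GENOME_WIDE_P,
                               exposure_instruments=None, log=None) -> list[str]:
    """Mediators with significant exposure->mediator and mediator->outcome MR.

    Each mediator must carry at least one strong instrument (p < 5e-8);
    mediators without instruments are excluded with a log entry.
    """
    if exposure_instruments is None:
        exposure_instruments = exposure.loc[
            exposure["p"] < p_instrument, "variant_id"].tolist()
    selected = []
    for name, med in mediators.items():
        inst = _mediator_instruments(med, p_instrument)
        if inst.empty:
            if log is not None:
                log.append(f"{name}: no instrument with p < {p_instrument:g}")
            continue
        p1 = _ivw_pair(exposure, med, exposure_instruments)
        p2 = _ivw_pair(med, outcome, inst["variant_id"].tolist())
        if p1 <= p_em and p2 <= p_mo:
            selected.append(name)
    return selected


def prune_correlated_mediators(candidates, mediator_corr, strength,
                               r_max: float = 0.1) -> list[str]:
    """Greedy forward-stepwise pruning of correlated mediators.

    Candidates are admitted in decreasing mediation strength; a candidate is
    rejected if its absolute correlation with any admitted mediator exceeds
    ``r_max``. The output therefore has pairwise |corr| <= r_max.
    """
    candidates = list(candidates)
    corr = np.asarray(mediator_corr, dtype=float)
    strength = np.asarray(strength, dtype=float)
    order = np.argsort(-np.abs(strength), kind="stable")
    admitted: list[int] = []
    for i in order:
        if all(abs(corr[i, j]) <= r_max for j in admitted):
            admitted.append(int(i))
    return [candidates[i] for i in admitted]


def greedy_ld_filter(ids, ld: pd.DataFrame, strengths, r2_max: float) -> list[str]:
    """Greedy independent-instrument filter on a user-supplied LD matrix."""
    ids = list(ids)
    order = np.argsort(np.asarray(strengths, dtype=float), kind="stable")
    kept: list[str] = []
    for i in order:  # ascending p-value
        vid = ids[i]
        if all(float(ld.loc[vid, kj]) ** 2 <= r2_max for kj in kept):
            kept.append(vid)
    return kept


def build_summary_data(exposure: pd.DataFrame, mediators: dict,
                       outcome: pd.DataFrame, p_em: float = 0.05,
                       p_mo: float = 0.05, r_max: float = 0.1,
                       mediator_corr: pd.DataFrame | None = None,
                       ld: pd.DataFrame | None = None, r2_max: float = 0.001,
                       p_instrument: float = GENOME_WIDE_P):
    """Assemble a mediation model from harmonized association tables.

    Returns (SummaryData, provenance dict). Exposure instruments are
    genome-wide significant, Steiger-filtered against the outcome and every
    selected mediator. Mediator instruments are genome-wide significant,
    Steiger-filtered against exposure and outcome, each owned by the
    mediator where it is most significant. Palindromic variants are dropped
    up front.
    """
    exposure = drop_palindromic(exposure)
    outcome = drop_palindromic(outcome)
    mediators = {name: drop_palindromic(t) for name, t in mediators.items()}
    log: list[str] = []

    exp_inst = exposure.loc[exposure["p"] < p_instrument, "variant_id"].tolist()
    if not exp_inst:
        raise InvalidParameterError("no genome-wide significant exposure instruments")
    exp_inst = steiger_filter(exposure, outcome, exp_inst)

    selected = select_candidate_mediators(
        exposure, mediators, outcome, p_em=p_em, p_mo=p_mo,
        p_instrument=p_instrument, exposure_instruments=exp_inst, log=log)
    if not selected:
        raise InvalidParameterError("no mediators passed the selection thresholds")

    # strength ranking |gamma_j * delta_j| from the univariable MRs
    strengths = []
    for name in selected:
        med = mediators[name]
        g = _aligned(exposure, med, exp_inst)
        gamma = ivw_total_effect(g["beta_l"].to_numpy(), g["beta_r"].to_numpy(),
                                 g["se_r"].to_numpy() ** 2).estimate
        inst = _mediator_instruments(med, p_instrument)["variant_id"].tolist()
        d = _aligned(med, outcome, inst)
        delta = ivw_total_effect(d["beta_l"].to_numpy(), d["beta_r"].to_numpy(),
                                 d["se_r"].to_numpy() ** 2).estimate
        strengths.append(abs(gamma * delta))
    if mediator_corr is not None and len(selected) > 1:
        corr = mediator_corr.loc[selected, selected].to_numpy()
        selected = prune_correlated_mediators(selected, corr, strengths, r_max=r_max)

    # mediator instruments: Steiger against exposure and outcome, owner by min p
    inst_owner: dict[str, tuple[int, float]] = {}
    for j, name in enumerate(selected):
        med = mediators[name]
        ids = _mediator_instruments(med, p_instrument)["variant_id"].tolist()
        ids = steiger_filter(med, outcome, ids)
        ids = steiger_filter(med, exposure, ids)
        sub = med.set_index("variant_id")
        for vid in ids:
            p = float(sub.loc[vid, "p"])
            if vid not in inst_owner or p < inst_owner[vid][1]:
                inst_owner[vid] = (j, p)
    if not inst_owner:
        raise InvalidParameterError("no mediator instruments survive filtering")
    med_inst = sorted(inst_owner, key=lambda v: inst_owner[v][1])
    med_inst = [v for v in med_inst if v not in set(exp_inst)]
    if ld is not None:
        med_inst = greedy_ld_filter(
            med_inst, ld, [inst_owner[v][1] for v in med_inst], r2_max)
        joint = exp_inst + med_inst
        keep = set(greedy_ld_filter(
            joint, ld, list(range(len(joint))), r2_max))
        exp_inst = [v for v in exp_inst if v in keep]
        med_inst = [v for v in med_inst if v in keep]

    # assemble the five blocks
    def effects(table, ids, ref):
        merged = _aligned(ref, table, ids).set_index("variant_id")
        return (np.array([merged.loc[v, "beta_r"] for v in ids]),
                np.array([merged.loc[v, "se_r"] for v in ids]))

    exp_idx = exposure.set_index("variant_id")
    beta_hat = exp_idx.loc[exp_inst, "beta"].to_numpy()
    c_hat, c_se = effects(outcome, exp_inst, exposure)
    C_hat = np.column_stack([effects(mediators[n], exp_inst, exposure)[0]
                             for n in selected])
    B_rows, b_vals, b_se, owner = [], [], [], []
    for vid in med_inst:
        j = inst_owner[vid][0]
        row = np.zeros(len(selected))
        for jj, name in enumerate(selected):
            tab = mediators[name].set_index("variant_id")
            if vid in tab.index:
                row[jj] = float(tab.loc[vid, "beta"])
        B_rows.append(row)
        out_tab = _aligned(mediators[selected[j]], outcome, [vid])
        b_vals.append(float(out_tab["beta_r"].iloc[0]))
        b_se.append(float(out_tab["se_r"].iloc[0]))
        owner.append(j)

    n_x = float(exposure["n"].median())
    n_m = float(np.median([mediators[n]["n"].median() for n in selected]))
    n_y = float(outcome["n"].median())
    data = SummaryData(
        beta_hat=beta_hat, C_hat=C_hat, B_hat=np.array(B_rows),
        c_hat=c_hat, b_hat=np.array(b_vals), n_X=n_x, n_M=n_m, n_Y=n_y,
        var_c=c_se**2, var_b=np.array(b_se) ** 2,
        owner=np.array(owner, dtype=int))
    provenance = {
        "exposure_instruments": exp_inst, "mediator_instruments": med_inst,
        "mediators": selected, "p_em": p_em, "p_mo": p_mo, "r_max": r_max,
        "log": log,
    }
    return data, provenance


def write_model(data: SummaryData, provenance: dict, out: str | Path) -> None:
    out = Path(out)
    data.to_dir(out)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
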