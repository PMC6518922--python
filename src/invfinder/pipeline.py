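"""End-to-end orchestration: detection → karyotyping → diversity →
recombination → clines, with TSV reports.

Every report starts with a ``# rng_seed=…`` header line so runs are
traceable; with the same config and seed the pipeline is deterministic
and reports are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from invfinder import clines as cl
from invfinder import diversity as dv
from invfinder import karyotype as kt
from invfinder import ld_network as ld
from invfinder import recombination as rc
from invfinder.config import AnalysisConfig
from invfinder.datatypes import MISSING, GenotypeMatrix, Pedigree
from invfinder.io import filter_genotypes, load_dataset

log = logging.getLogger(__name__)

STAGES = ("filter", "detect", "karyotype", "diversity", "recomb", "clines")


def _write_report(df: pd.DataFrame, path: Path, seed: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# rng_seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _stage_error(stage: str, exc: Exception) -> RuntimeError:
    return RuntimeError(f"[stage {stage}] {exc}")


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    gm: GenotypeMatrix | None = None,
    pedigree: Pedigree | None = None,
    stop_after: str = "clines",
) -> dict:
    """Run the full pipeline and write TSV reports into ``out_dir``.

    ``gm``/``pedigree`` may be passed directly (e.g. from the
    simulator); otherwise they are loaded from ``config.paths``.
    Failures abort with a stage-tagged message; reports written by
    earlier stages are preserved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    results: dict = {}

    try:
        if gm is None:
            gm, pedigree = load_dataset(
                config.paths["genotypes"],
                config.paths["map"],
                config.paths["metadata"],
                config.paths.get("pedigree"),
            )
        gm_filt, report = filter_genotypes(
            gm,
            maf_min=config.maf_min,
            min_called=config.min_called,
            max_individual_missing=config.max_individual_missing,
        )
        results["filter_report"] = pd.DataFrame([report])
        _write_report(results["filter_report"], out_dir / "filter_report.tsv", seed)
    except Exception as exc:  # noqa: BLE001
        raise _stage_error("filter", exc) from exc
    if stop_after == "filter":
        return results

    transect_rows = np.flatnonzero(
        gm_filt.individuals["source"].to_numpy() == "transect"
    )
    if transect_rows.size == 0:  # no metadata distinction: use everyone
        transect_rows = np.arange(gm_filt.n_individuals)
    gm_tr = gm_filt.take_individuals(transect_rows)

    try:
        socs = ld.detect_socs(gm_tr, config)
        results["socs"] = socs
    except Exception as exc:  # noqa: BLE001
        raise _stage_error("detect", exc) from exc
    if stop_after == "detect":
        _write_report(_soc_table(socs, {}), out_dir / "soc_table.tsv", seed)
        return results

    try:
        candidates, kary_table, pc1_var = _karyotype_stage(gm_tr, socs, config)
        results["candidates"] = candidates
        results["karyotypes"] = kary_table
        _write_report(_soc_table(socs, pc1_var, candidates), out_dir / "soc_table.tsv", seed)
        _write_report(kary_table, out_dir / "karyotype_table.tsv", seed)
    except Exception as exc:  # noqa: BLE001
        raise _stage_error("karyotype", exc) from exc
    if stop_after == "karyotype":
        return results

    try:
        div_table, div_tests = _diversity_stage(gm_tr, candidates, config)
        results["diversity"] = div_table
        results["diversity_tests"] = div_tests
        _write_report(div_table, out_dir / "diversity_table.tsv", seed)
        _write_report(div_tests, out_dir / "diversity_tests.tsv", seed)
    except Exception as exc:  # noqa: BLE001
        raise _stage_error("diversity", exc) from exc
    if stop_after == "diversity":
        return results

    if pedigree is not None:
        try:
            recomb = _recombination_stage(gm_filt, pedigree, candidates, config)
            results.update(recomb)
            _write_report(recomb["parent_karyotypes"], out_dir / "parent_karyotypes.tsv", seed)
            _write_report(recomb["crossover_events"], out_dir / "crossover_events.tsv", seed)
            _write_report(recomb["suppression"], out_dir / "suppression_summary.tsv", seed)
            _write_report(recomb["orientation"], out_dir / "orientation_calls.tsv", seed)
        except Exception as exc:  # noqa: BLE001
            raise _stage_error("recomb", exc) from exc
    if stop_after == "recomb":
        return results

    try:
        cline_table = _cline_stage(gm_tr, candidates, config)
        results["clines"] = cline_table
        _write_report(cline_table, out_dir / "cline_table.tsv", seed)
    except Exception as exc:  # noqa: BLE001
        raise _stage_error("clines", exc) from exc
    return results


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _overlapping(socs: list[ld.SOC]) -> set[str]:
    """soc_ids whose map interval overlaps another SOC on the same LG."""
    out = set()
    for a in socs:
        for b in socs:
            if (
                a is not b
                and a.linkage_group == b.linkage_group
                and a.start_cm <= b.end_cm
                and b.start_cm <= a.end_cm
            ):
                out.add(a.soc_id)
                out.add(b.soc_id)
    return out


def _karyotype_stage(gm: GenotypeMatrix, socs, config):
    overlapped = _overlapping(socs)
    distances = gm.individuals["transect_distance"].to_numpy(dtype=float)
    candidates, rows = [], []
    pc1_var: dict[str, float] = {}
    for soc in socs:
        k = 6 if soc.soc_id in overlapped else 3
        pca = kt.region_pca(
            gm, soc.linkage_group, soc.start_cm, soc.end_cm, scale=config.scale_pca
        )
        pc1_var[soc.soc_id] = float(pca.variance_fraction[0])
        try:
            assignment = kt.assign_groups(
                pca, k=k, restarts=config.kmeans_restarts,
                seed=config.rng_seed, soc_id=soc.soc_id,
            )
        except ValueError as exc:
            log.warning("%s: grouping failed (%s)", soc.soc_id, exc)
            continue
        cand = kt.candidate_filter(
            soc, pca, assignment,
            pc1_min=config.pc1_min_variance,
            max_intermediate_fraction=config.max_intermediate_fraction,
            intermediate_sd=config.intermediate_sd,
        )
        if cand.status == "accepted":
            try:
                cand.assignment = kt.orient_and_label(
                    assignment, pca, distances, crab_end_window=config.crab_end_window
                )
                cand.k = k
            except ValueError as exc:
                log.warning("%s: orientation failed (%s)", soc.soc_id, exc)
                cand.status = "rejected_intermediates"
        candidates.append(cand)
        labels = cand.assignment.labels
        for i, iid in enumerate(gm.individual_ids):
            g = int(cand.assignment.group[i])
            rows.append(
                (
                    iid,
                    soc.soc_id,
                    g,
                    labels.get(g, "NA"),
                    float(pca.scores[i, 0]),
                    float(pca.scores[i, 1]) if pca.scores.shape[1] > 1 else np.nan,
                )
            )
    table = pd.DataFrame(
        rows, columns=["individual_id", "soc_id", "group", "label", "PC1", "PC2"]
    )
    return candidates, table, pc1_var


def _soc_table(socs, pc1_var: dict, candidates=None) -> pd.DataFrame:
    status = {}
    if candidates:
        status = {c.soc.soc_id: c.status for c in candidates}
    return pd.DataFrame(
        [
            {
                "soc_id": s.soc_id,
                "linkage_group": s.linkage_group,
                "size_cm": s.size_cm,
                "start_cm": s.start_cm,
                "end_cm": s.end_cm,
                "n_snps": s.n_snps,
                "n_contigs": s.n_contigs,
                "median_r2": s.median_r2,
                "phi": s.phi_at_extraction,
                "pc1_variance": pc1_var.get(s.soc_id, np.nan),
                "status": status.get(s.soc_id, "NA"),
            }
            for s in socs
        ]
    )


def _contig_regions(gm: GenotypeMatrix, cols: np.ndarray, length: float) -> pd.DataFrame:
    """Probe-like regions: one per contig among the given SNP columns."""
    sub = gm.loci.iloc[cols]
    regions = (
        sub.groupby("contig", sort=True)
        .agg(start=("contig_pos", lambda p: int(p.min()) - 1), end=("contig_pos", "max"))
        .reset_index()
    )
    regions["end"] = regions["end"].astype(int) + 1
    regions["effective_length"] = length
    return regions


def _diversity_stage(gm: GenotypeMatrix, candidates, config):
    div_rows = []
    comparisons: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cand in candidates:
        if cand.status != "accepted":
            continue
        soc = cand.soc
        labelled = cand.assignment
        inside = gm.loci_in_interval(soc.linkage_group, soc.start_cm, soc.end_cm)
        on_lg = np.flatnonzero(
            gm.loci["linkage_group"].to_numpy() == soc.linkage_group
        )
        collinear = np.setdiff1d(on_lg, inside)
        groups = {
            lab: np.flatnonzero(labelled.group == g)
            for g, lab in labelled.labels.items()
        }
        hets = [lab for lab in groups if _is_het(lab)]
        homs = [lab for lab in groups if not _is_het(lab)]
        for lab, rows in groups.items():
            if rows.size == 0:
                continue
            h_in = dv.observed_heterozygosity(gm, rows, inside)
            h_out = (
                dv.observed_heterozygosity(gm, rows, collinear)
                if collinear.size
                else np.array([np.nan])
            )
            div_rows.append(
                {
                    "soc_id": soc.soc_id,
                    "group": lab,
                    "n_individuals": int(rows.size),
                    "hobs_inside": float(np.nanmean(h_in)),
                    "hobs_collinear": float(np.nanmean(h_out)),
                }
            )
            if _is_het(lab) and collinear.size:
                comparisons[f"{soc.soc_id}:{lab}:inside_vs_collinear_hobs"] = (
                    h_in,
                    h_out,
                )
        # pi and dxy per probe region between homokaryotype pairs
        regions = _contig_regions(gm, inside, config.effective_region_length)
        for i, lab_x in enumerate(homs):
            for lab_y in homs[i + 1 :]:
                rx, ry = groups[lab_x], groups[lab_y]
                if rx.size < 2 or ry.size < 2:
                    continue
                pi_x = dv.pi_regions(gm, rx, regions, config.effective_region_length)
                pi_y = dv.pi_regions(gm, ry, regions, config.effective_region_length)
                dxy = dv.dxy_regions(
                    gm, rx, ry, regions, config.effective_region_length
                )
                div_rows.append(
                    {
                        "soc_id": soc.soc_id,
                        "group": f"{lab_x}_vs_{lab_y}",
                        "n_individuals": int(rx.size + ry.size),
                        "pi_x": float(np.nanmean(pi_x)),
                        "pi_y": float(np.nanmean(pi_y)),
                        "dxy": float(np.nanmean(dxy)),
                    }
                )
                if len(pi_x) >= 2:
                    comparisons[f"{soc.soc_id}:{lab_x}_vs_{lab_y}:pi_homokaryotypes"] = (
                        pi_x,
                        pi_y,
                    )
    div_table = pd.DataFrame(div_rows)
    tests = dv.compare_groups(comparisons, alpha=config.alpha) if comparisons else []
    test_table = pd.DataFrame(
        [
            {
                "comparison": t.comparison,
                "W": t.statistic,
                "p": t.p_value,
                "p_holm": t.p_adjusted,
                "significant": t.significant,
            }
            for t in tests
        ]
    )
    return div_table, test_table


def _is_het(label: str) -> bool:
    return rc._karyotype_class(label) == "RA"


def _recombination_stage(gm: GenotypeMatrix, pedigree: Pedigree, candidates, config):
    accepted = [c for c in candidates if c.status == "accepted"]
    parent_ids = sorted(
        {
            p
            for fid in pedigree.family_ids
            for p in (
                pedigree.family(fid)["mother_id"],
                pedigree.family(fid)["father_id"],
            )
            if p is not None and p in gm.individual_ids
        }
    )
    pk = rc.infer_parent_karyotypes(
        gm,
        accepted,
        parent_ids,
        seed=config.rng_seed,
        restarts=config.kmeans_restarts,
        min_call_rate=config.min_parent_call_rate,
        crab_end_window=config.crab_end_window,
    )
    events: list[rc.CrossoverEvent] = []
    case_rows = []
    orient_rows = []
    for fid in pedigree.family_ids:
        family = pedigree.family(fid)
        try:
            informative = rc.informative_sites_qc(
                gm, family, segregation_p=config.segregation_p
            )
        except ValueError as exc:
            log.warning("family %s skipped: %s", fid, exc)
            continue
        for pid, cols in informative.items():
            lgs = np.unique(gm.loci["linkage_group"].to_numpy()[cols])
            for lg in lgs:
                try:
                    ev, _ = rc.call_crossovers(
                        gm, fid, pid, family["offspring_ids"], cols, int(lg),
                        large_gap_cm=config.large_gap_cm,
                    )
                except ValueError:
                    continue
                events.extend(ev)
            for cand in accepted:
                soc = cand.soc
                n_inside = (
                    (gm.loci["linkage_group"].to_numpy()[cols] == soc.linkage_group)
                    & (gm.loci["cm_position"].to_numpy()[cols] >= soc.start_cm)
                    & (gm.loci["cm_position"].to_numpy()[cols] <= soc.end_cm)
                ).sum()
                if n_inside < 2:
                    continue
                for oid in family["offspring_ids"]:
                    case_rows.append((pid, oid, soc.soc_id))
                label = pk.loc[pid, soc.soc_id] if pid in pk.index else "NA"
                if rc._karyotype_class(label) in ("RR", "AA"):
                    try:
                        oc = rc.orientation_classify(
                            gm, fid, pid, family["offspring_ids"], cols, soc
                        )
                        oc["parent_id"] = pid
                        oc["parent_karyotype"] = label
                        orient_rows.append(oc)
                    except ValueError:
                        pass
    cases = pd.DataFrame(case_rows, columns=["parent_id", "offspring_id", "soc_id"])
    suppression = rc.suppression_summary(events, pk, accepted, cases)
    ev_table = pd.DataFrame([vars(e) for e in events]) if events else pd.DataFrame(
        columns=[f.name for f in rc.CrossoverEvent.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    )
    orientation = (
        pd.concat(orient_rows, ignore_index=True)
        if orient_rows
        else pd.DataFrame(
            columns=[
                "offspring_id", "soc_id", "crossovers_under_R",
                "crossovers_under_A", "call", "parent_id", "parent_karyotype",
            ]
        )
    )
    return {
        "parent_karyotypes": pk.rename_axis("parent_id").reset_index(),
        "crossover_events": ev_table,
        "suppression": suppression,
        "orientation": orientation,
    }


def _cline_stage(gm: GenotypeMatrix, candidates, config) -> pd.DataFrame:
    distances = gm.individuals["transect_distance"].to_numpy(dtype=float)
    rows = []
    clinal_sets = []
    for cand in candidates:
        if cand.status != "accepted":
            continue
        labelled = cand.assignment
        arrangements = sorted(
            {a for lab in labelled.labels.values() for a in kt._split_label(lab)}
        )
        derived = [a for a in arrangements if a != "R"]
        for arr in derived:
            copies = kt.arrangement_copies(labelled, arr)
            name = (
                cand.soc.soc_id if len(derived) == 1 else f"{cand.soc.soc_id}:{arr}"
            )
            try:
                fits = {
                    "constant": cl.fit_cline(copies, distances, "constant"),
                    "symmetric": cl.fit_cline(
                        copies, distances, "symmetric", n_starts=config.cline_starts
                    ),
                    "asymmetric": cl.fit_cline(
                        copies, distances, "asymmetric", n_starts=config.cline_starts
                    ),
                }
            except ValueError as exc:
                log.warning("%s: cline fitting skipped (%s)", name, exc)
                continue
            sel = cl.select_model(
                fits, daic_min=config.daic_min, dev_min=config.deviance_min
            )
            best = fits[sel["selected"]]
            row = {
                "soc_id": name,
                "model": sel["selected"],
                "clinal": sel["clinal"],
                "daic_vs_constant": sel["daic"],
                "deviance_explained": fits["symmetric"].deviance_explained,
                "loglik": best.loglik,
                "aic": best.aic,
            }
            if sel["clinal"]:
                fit = fits["symmetric"] if sel["selected"] == "symmetric" else best
                row.update(
                    centre=fit.params.get("centre"),
                    width=fit.params.get("width", fit.params.get("width_crab")),
                    p_crab=fit.params.get("p_crab"),
                    p_wave=fit.params.get("p_wave"),
                )
                for end in ("Crab", "Wave"):
                    ft = cl.fixation_test(
                        copies, distances, fit, end=end,
                        alpha=config.alpha, n_starts=config.cline_starts,
                    )
                    row[f"fixed_{end.lower()}"] = ft["fixed_equivalent"]
                    row[f"fixation_p_{end.lower()}"] = ft["p_value"]
                clinal_sets.append((copies, distances, fit))
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(clinal_sets) >= 2:
        lo, hi = distances.min(), distances.max()
        cgrid = np.arange(*config.profile_centre_grid[:2], config.profile_centre_grid[2])
        cgrid = cgrid[(cgrid >= lo) & (cgrid <= hi)]
        wstart, wstop, wstep = config.profile_logwidth_grid
        wgrid = np.exp(np.arange(wstart, wstop + 1e-9, wstep))
        for param, grid in (("centre", cgrid), ("width", wgrid)):
            prof = cl.profile_shared(clinal_sets, parameter=param, grid=grid)
            table.attrs[f"profile_{param}"] = {
                "best_shared_value": prof.best_shared_value,
                "two_dll": prof.two_dll,
                "df": prof.df,
                "p_value": prof.p_value,
            }
    return table
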