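"""Full-report assembly: integrate, fit, locate, correlate, write.

:func:`run_report` chains every analysis stage on one pair of input tables
and writes a self-contained report directory:

* ``integrated.tsv`` / ``unpaired.json`` — the operon-array join;
* ``size_summary.tsv`` — per-group descriptives (mean, quartiles, n);
* ``fit_results.tsv`` — per-group geometric parameter and goodness-of-fit
  p-value alongside the strand-specific position-uniformity p-values;
* ``results.json`` — every computed number, machine-readable;
* ``location_hist_<strand>.tsv`` — integer-degree polar histogram tables;
* ``profiles.tsv`` / ``multiplicity_curve.tsv`` — the multiplicity stage;
* ``manifest.json`` — config snapshot, seeds, input digests, version;
* ``figures/*.png`` — optional.

Group hierarchy: Class 1 (everything) → Type I / Type III → the four
well-represented subtypes I-B, I-C, I-E, I-F; systems with other subtype
labels are pooled as "other" and excluded from subtype-level tests.
Groups below ``min_group_n`` systems are reported with an ``underpowered``
flag rather than suppressed.  Every figure number is also present in a
stage output file — there are no figure-only results.
"""
from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .integrate import associate_arrays, filter_dataset, segregate_by_strand
from .io import (
    read_array_table,
    read_cas_table,
    write_integrated_table,
    write_unpaired_report,
)
from .location import polar_histogram, positions_from_systems, uniformity_test
from .multiplicity import (
    multiplicity_curve,
    profile_genomes,
    profiles_to_frame,
    proximal_size_association,
    single_cas_fraction,
)
from .records import ArrayRecord, CasOperon, FilterCriteria, IntegratedSystem
from .sizedist import (
    ArraySizeModel,
    SizeSample,
    kruskal_wallis,
    welch_t_test,
)

MAIN_SUBTYPES = ("I-B", "I-C", "I-E", "I-F")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _subtype_label(op: CasOperon) -> str:
    if op.subtype in MAIN_SUBTYPES:
        return op.subtype
    return "other"


def build_groups(
    systems: Sequence[IntegratedSystem],
) -> Dict[str, List[IntegratedSystem]]:
    """Class 1 / Type I / Type III / subtype grouping of systems."""
    groups: Dict[str, List[IntegratedSystem]] = {"Class 1": list(systems)}
    for s in systems:
        groups.setdefault(f"Type {s.operon.system_type}", []).append(s)
    for s in systems:
        if s.operon.system_type == "I":
            groups.setdefault(_subtype_label(s.operon), []).append(s)
    return {k: v for k, v in groups.items() if v}


def group_counts(
    group: Sequence[IntegratedSystem],
    all_arrays: Sequence[ArrayRecord],
    size_scope: str = "proximal",
) -> np.ndarray:
    """Spacer counts for a group under the chosen scope.

    ``proximal`` takes one count per system (the cas-proximal array);
    ``all`` takes every distinct array on the replicons the group's
    systems live on.
    """
    if size_scope == "proximal":
        return np.array([s.proximal_array.n_spacers for s in group], dtype=np.int64)
    if size_scope != "all":
        raise ValueError("size_scope must be 'proximal' or 'all'")
    accs = {s.accession for s in group}
    seen = set()
    counts = []
    for a in all_arrays:
        key = (a.accession, a.array_id)
        if a.accession in accs and key not in seen:
            seen.add(key)
            counts.append(a.n_spacers)
    return np.array(counts, dtype=np.int64)


def run_report(
    arrays,
    cas,
    out_dir,
    seed: int = 0,
    n_boot: int = 999,
    min_group_n: int = 30,
    size_scope: str = "proximal",
    criteria: Optional[FilterCriteria] = None,
    figures: bool = True,
    command: str = "report",
) -> dict:
    """Run every analysis stage and write the report directory.

    ``arrays`` and ``cas`` may be file paths (canonical TSV dialects) or
    already-loaded record lists.  Returns the full results dictionary that
    is also written to ``results.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests = {}
    if isinstance(arrays, (str, Path)):
        digests["arrays"] = _sha256(arrays)
        arrays = read_array_table(arrays)
    if isinstance(cas, (str, Path)):
        digests["cas"] = _sha256(cas)
        cas = read_cas_table(cas)
    criteria = criteria or FilterCriteria()

    arrays_f, cas_f = filter_dataset(arrays, cas, criteria)
    systems, unpaired = associate_arrays(cas_f, arrays_f)
    write_integrated_table(systems, out / "integrated.tsv")
    write_unpaired_report(unpaired, out / "unpaired.json")

    seed_seq = np.random.SeedSequence(seed)
    results: dict = {
        "n_arrays_input": len(arrays),
        "n_operons_input": len(cas),
        "n_arrays_filtered": len(arrays_f),
        "n_operons_filtered": len(cas_f),
        "n_systems": len(systems),
        "n_unpaired": len(unpaired),
        "size_scope": size_scope,
    }

    # ----- size distributions per group -------------------------------
    groups = build_groups(systems)
    group_results = {}
    samples: Dict[str, SizeSample] = {}
    child_seeds = iter(seed_seq.spawn(len(groups) + 1))
    for label, members in groups.items():
        counts = group_counts(members, arrays_f, size_scope)
        if counts.size == 0:
            continue
        sample = SizeSample(label=label, counts=counts)
        samples[label] = sample
        gseed = int(next(child_seeds).generate_state(1)[0] % (2**31))
        res = ArraySizeModel(counts, label=label).fit(n_boot=n_boot, seed=gseed)
        entry = res.to_dict()
        entry["underpowered"] = sample.n < min_group_n
        group_results[label] = entry
    results["groups"] = group_results

    tests: dict = {}
    if "Type I" in samples and "Type III" in samples:
        t, df, p = welch_t_test(samples["Type I"], samples["Type III"])
        tests["welch_typeI_vs_typeIII"] = {"t": t, "df": df, "p": p}
    kw_groups = [samples[s] for s in MAIN_SUBTYPES if s in samples]
    if len(kw_groups) >= 2:
        h, df, p = kruskal_wallis(kw_groups)
        tests["kruskal_subtypes"] = {
            "H": h,
            "df": df,
            "p": p,
            "subtypes": [g.label for g in kw_groups],
        }
    results["tests"] = tests

    # ----- location ---------------------------------------------------
    by_strand = segregate_by_strand(systems)
    location: dict = {"by_strand": {}, "by_group": {}}
    hists = {}
    for strand in ("+", "-"):
        members = by_strand[strand]
        positions = positions_from_systems(members)
        hist = polar_histogram(positions, strand=strand)
        hists[strand] = hist
        pd.DataFrame(
            {"degree": np.arange(360), "count": hist.bin_counts}
        ).to_csv(out / f"location_hist_{'plus' if strand == '+' else 'minus'}.tsv",
                 sep="\t", index=False)
        if positions:
            u = uniformity_test(positions, strand=strand, min_n=min_group_n)
            location["by_strand"][strand] = vars(u).copy()
    for label, members in groups.items():
        per_group = {}
        seg = segregate_by_strand(members)
        for strand in ("+", "-"):
            pos = positions_from_systems(seg[strand])
            if pos:
                u = uniformity_test(pos, strand=strand, min_n=min_group_n)
                per_group[strand] = vars(u).copy()
        location["by_group"][label] = per_group
    results["location"] = location

    # ----- multiplicity -----------------------------------------------
    profiles = profile_genomes(systems, arrays_f)
    profiles_to_frame(profiles).to_csv(out / "profiles.tsv", sep="\t", index=False)
    from collections import Counter

    operon_counts = Counter(o.accession for o in cas_f)
    multiplicity: dict = {}
    if operon_counts:
        multiplicity["single_cas_fraction"] = single_cas_fraction(operon_counts)
    curve = multiplicity_curve(profiles)
    curve.to_csv(out / "multiplicity_curve.tsv", sep="\t", index=False)
    multiplicity["curve"] = curve.to_dict(orient="records")
    multiplicity["rho"] = {}
    for variant in ("aggregated_proportion", "per_genome"):
        try:
            rho = proximal_size_association(profiles, variant=variant)
            multiplicity["rho"][variant] = vars(rho).copy()
        except ValueError as exc:
            multiplicity["rho"][variant] = {"error": str(exc)}
    results["multiplicity"] = multiplicity

    # ----- tabular mirrors --------------------------------------------
    size_rows = []
    for label, entry in group_results.items():
        s = entry["summary"]
        size_rows.append(
            {
                "group": label,
                "mean": round(s["mean"], 3),
                "q1": s["q1"],
                "median": s["median"],
                "q3": s["q3"],
                "systems": s["n"],
                "underpowered": int(entry["underpowered"]),
            }
        )
    pd.DataFrame(size_rows).to_csv(out / "size_summary.tsv", sep="\t", index=False)

    fit_rows = []
    for label, entry in group_results.items():
        row = {
            "group": label,
            "geometric_p_hat": round(entry["fits"]["geometric"]["theta"], 5),
            "gof_p_geometric": entry.get("gof", {}).get("geometric", {}).get("p_value"),
            "underpowered": int(entry["underpowered"]),
        }
        for strand, key in (("+", "uniform_plus_p"), ("-", "uniform_minus_p")):
            u = location["by_group"].get(label, {}).get(strand)
            row[key] = None if u is None else u["p_value"]
        fit_rows.append(row)
    pd.DataFrame(fit_rows).to_csv(out / "fit_results.tsv", sep="\t", index=False)

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_json_default)
        fh.write("\n")

    # ----- figures ----------------------------------------------------
    if figures:
        _write_figures(out, samples, group_results, hists, curve)

    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "seed": seed,
        "n_boot": n_boot,
        "min_group_n": min_group_n,
        "size_scope": size_scope,
        "criteria": {
            "allow_replicon_kinds": sorted(criteria.allow_replicon_kinds),
            "exclude_questionable": criteria.exclude_questionable,
            "allowed_classes": sorted(criteria.allowed_classes),
            "allowed_types": sorted(criteria.allowed_types),
            "require_cas1": criteria.require_cas1,
        },
        "input_digests": digests,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return results


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_figures(out: Path, samples, group_results, hists, curve) -> None:
    import matplotlib.pyplot as plt

    from . import plotting

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    ordered = [samples[k] for k in samples]
    if ordered:
        for log10, name in ((False, "boxplots.png"), (True, "boxplots_log10.png")):
            fig = plotting.boxplots(ordered, log10=log10)
            fig.savefig(figdir / name, dpi=120)
            plt.close(fig)
    if "Class 1" in samples:
        entry = group_results["Class 1"]
        fits = {f: r["theta"] for f, r in entry["fits"].items()}
        for builder, name in (
            (plotting.size_histogram, "size_histogram.png"),
            (plotting.cdf_comparison, "cdf_comparison.png"),
        ):
            fig = builder(samples["Class 1"], fits)
            fig.savefig(figdir / name, dpi=120)
            plt.close(fig)
        best = entry["best_family"]
        fig = plotting.probability_plot(
            samples["Class 1"], best, entry["fits"][best]["theta"]
        )
        fig.savefig(figdir / "probability_plot.png", dpi=120)
        plt.close(fig)
    for strand, hist in hists.items():
        if hist.total:
            fig = plotting.polar_plot(hist)
            fig.savefig(
                figdir / f"polar_{'plus' if strand == '+' else 'minus'}.png", dpi=120
            )
            plt.close(fig)
    if len(curve):
        fig = plotting.multiplicity_histograms(curve)
        fig.savefig(figdir / "multiplicity.png", dpi=120)
        plt.close(fig)
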