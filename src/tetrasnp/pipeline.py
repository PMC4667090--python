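"""End-to-end pipeline: simulate -> observe -> classify -> genotype -> stats.

Every stage derives its RNG stream from the single run seed, so a run is
byte-reproducible from its manifest. Outputs are plain-text tables (TSV/JSON)
under the run directory:

    progenitors.fasta, panel.fasta   simulated sequences
    truth.tsv                        planted variant ground truth
    observations.tsv                 per-genotype zygosity metadata
    composition.tsv                  inferred copy composition per locus
    variants.tsv                     classified variable sites
    markers.tsv, marker_summary.json marker report (counts + PIC) per group
    hrm_calls.tsv                    HRM cluster genotype calls
    segregation.tsv                  RIL 1:1 chi-square tests
    recovery.json                    classifier-vs-truth scoring
    manifest.json                    config, seed, stage status, version
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, ampliconobs, classify, hrmsim, markerstats, simpanel


@dataclass(frozen=True)
class HRMParams:
    noise_sd: float = 0.0
    amplicon_length: int = 100
    mismatch_penalty: float = hrmsim.DEFAULT_MISMATCH_PENALTY
    width: float = hrmsim.DEFAULT_WIDTH
    salt_offset: float = hrmsim.DEFAULT_SALT_OFFSET
    cluster_threshold: float = hrmsim.DEFAULT_CLUSTER_THRESHOLD
    qc_fail_prob: float = 0.0
    qc_window: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    sim: simpanel.SimConfig
    ril: simpanel.RILConfig = simpanel.RILConfig()
    hrm: HRMParams = HRMParams()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path | str, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        run_seed = seed if seed is not None else int(raw.get("seed", 0))
        sim_kwargs = dict(raw.get("sim", {}))
        sim_kwargs.setdefault("n_loci", 50)
        sim_kwargs["seed"] = run_seed
        ril_kwargs = dict(raw.get("ril", {}))
        ril_kwargs["seed"] = run_seed + 1
        return cls(
            sim=simpanel.SimConfig(**sim_kwargs),
            ril=simpanel.RILConfig(**ril_kwargs),
            hrm=HRMParams(**raw.get("hrm", {})),
            seed=run_seed,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sim": dataclasses.asdict(self.sim),
            "ril": dataclasses.asdict(self.ril),
            "hrm": dataclasses.asdict(self.hrm),
        }


def build_observations(
    panel: simpanel.PanelTruth,
) -> tuple[
    dict[str, ampliconobs.AmpliconObservation],
    dict[str, ampliconobs.AmpliconObservation],
    dict[str, dict[str, ampliconobs.AmpliconObservation]],
]:
    """Superpose copies into per-genotype consensus observations.

    Returns (progA by locus, progB by locus, {locus: {variety: observation}}).
    Diploid progenitors superpose their 1-2 copies; tetraploid varieties
    superpose all retained copies.
    """
    prog_a: dict[str, ampliconobs.AmpliconObservation] = {}
    prog_b: dict[str, ampliconobs.AmpliconObservation] = {}
    varieties: dict[str, dict[str, ampliconobs.AmpliconObservation]] = {}
    for locus in panel.loci:
        prog_a[locus.locus_id] = ampliconobs.observe_amplicon(
            locus.a_copies, locus.locus_id, "progA"
        )
        prog_b[locus.locus_id] = ampliconobs.observe_amplicon(
            locus.b_copies, locus.locus_id, "progB"
        )
        varieties[locus.locus_id] = {
            v: ampliconobs.observe_amplicon(
                list(panel.variety_copies(locus.locus_id, v).values()),
                locus.locus_id,
                v,
            )
            for v in panel.variety_ids
        }
    return prog_a, prog_b, varieties


def majority_observation(
    panel_obs: Mapping[str, ampliconobs.AmpliconObservation],
) -> ampliconobs.AmpliconObservation:
    """Per-position modal letter across varieties.

    Used as the composition-inference representative so that low-frequency
    segregating alleles do not masquerade as copy-structure mismatches.
    """
    observations = list(panel_obs.values())
    letters = []
    for column in zip(*(o.sequence for o in observations)):
        counts: dict[str, int] = {}
        for letter in column:
            counts[letter] = counts.get(letter, 0) + 1
        letters.append(max(sorted(counts), key=counts.get))
    first = observations[0]
    return ampliconobs.AmpliconObservation(
        first.locus_id, "panel-consensus", "".join(letters)
    )


def classify_panel(
    panel: simpanel.PanelTruth,
) -> tuple[list[classify.CopyComposition], list[classify.VariantSite], pd.DataFrame]:
    """Infer copy composition and classify sites for every sequenceable locus."""
    prog_a, prog_b, var_obs = build_observations(panel)
    compositions: list[classify.CopyComposition] = []
    sites: list[classify.VariantSite] = []
    for locus in panel.loci:
        if not locus.sequenceable:
            continue
        obs = var_obs[locus.locus_id]
        consensus = majority_observation(obs)
        comp = classify.infer_copy_composition(
            consensus, prog_a[locus.locus_id], prog_b[locus.locus_id]
        )
        compositions.append(comp)
        if comp.explained:
            sites.extend(
                classify.classify_sites(
                    obs, prog_a[locus.locus_id], prog_b[locus.locus_id], comp
                )
            )
    comp_table = pd.DataFrame(
        {
            "locus": [c.locus_id for c in compositions],
            "hypothesis": [c.hypothesis for c in compositions],
            "mismatch_count": [c.mismatch_count for c in compositions],
            "explained": [c.explained for c in compositions],
            "copies": ["+".join(c.copy_labels) for c in compositions],
        }
    )
    return compositions, sites, comp_table


def score_recovery(
    panel: simpanel.PanelTruth, sites: list[classify.VariantSite]
) -> dict:
    """Compare classified sites with generator truth (sequenceable loci only).

    Recovery = fraction of observable truth sites found with the correct
    category; false categories = resolved calls at truth positions with the
    wrong category, or at unplanted positions.
    """
    truth: dict[tuple[str, int], set[str]] = {}
    for locus in panel.loci:
        if not locus.sequenceable:
            continue
        for t in panel.observable_sites(locus):
            truth.setdefault((locus.locus_id, t.position + 1), set()).add(t.category)
    called: dict[tuple[str, int], str] = {
        (s.locus_id, s.position): s.category
        for s in sites
        if s.category != "unresolved"
    }
    recovered = sum(
        1
        for key, cats in truth.items()
        if called.get(key) in cats
        or (called.get(key) == "SNP" and "SNP" in cats)
    )
    false_calls = [
        {"locus": k[0], "pos_1based": k[1], "category": cat}
        for k, cat in called.items()
        if k not in truth or cat not in truth[k]
    ]
    return {
        "n_truth_sites": len(truth),
        "n_recovered_correct": recovered,
        "recovery_fraction": recovered / len(truth) if truth else 1.0,
        "n_false_categories": len(false_calls),
        "false_calls": false_calls[:50],
    }


def _marker_calls_from_sites(
    sites: list[classify.VariantSite], variety_ids: list[str]
) -> pd.DataFrame:
    """Marker x variety call matrix from classified SNP sites, after per-locus
    full-LD reduction (one marker per r2=1 class)."""
    snp_sites = [s for s in sites if s.category == "SNP" and s.calls]
    by_locus: dict[str, list[classify.VariantSite]] = {}
    for s in snp_sites:
        by_locus.setdefault(s.locus_id, []).append(s)
    rows = {}
    for locus_id, locus_sites in sorted(by_locus.items()):
        fragment = [
            (
                s.position,
                f"{s.locus_id}:{s.position}",
                [s.calls.get(v) for v in variety_ids],
            )
            for s in locus_sites
        ]
        keep = set(markerstats.marker_selection(fragment))
        for s in locus_sites:
            marker_id = f"{s.locus_id}:{s.position}"
            if marker_id in keep:
                rows[marker_id] = [s.calls.get(v) for v in variety_ids]
    return pd.DataFrame.from_dict(rows, orient="index", columns=variety_ids)


def _hrm_amplicon(
    locus: simpanel.LocusModel,
    site: classify.VariantSite,
    length: int,
) -> dict[str, str] | None:
    """Nested subgenome-specific amplicon around a SNP, one per allele.

    SNPs that could not be anchored to one subgenome (both copies share the
    reference base at the column) default to the A-genome template.
    """
    if site.alleles is None:
        return None
    genome = site.subgenome if site.subgenome in ("A", "B") else "A"
    copies = locus.a_copies if genome == "A" else locus.b_copies
    seq = copies[0]
    pos = site.position - 1
    start = max(0, min(pos - length // 2, len(seq) - length))
    end = start + length
    if end > len(seq):
        return None
    window = seq[start:end]
    offset = pos - start
    return {
        allele: window[:offset] + allele + window[offset + 1 :]
        for allele in site.alleles
    }


def hrm_genotype_panel(
    genotypes: Mapping[str, tuple[str, str]],
    amplicons: Mapping[str, str],
    params: HRMParams,
    seed: int,
    cycles: np.ndarray | None = None,
) -> tuple[list[hrmsim.GenotypeCall], list[str]]:
    """Simulate melt curves for a panel of samples and cluster genotypes.

    ``genotypes`` maps sample id -> allele pair; heterozygous pairs produce
    heteroduplex species. Samples failing the amplification QC (simulated
    late amplification with probability ``qc_fail_prob``) are excluded and
    returned as missing.
    """
    rng = np.random.default_rng(seed)
    samples = list(genotypes)

    excluded: list[str] = []
    if params.qc_fail_prob > 0:
        if cycles is None:
            cycles = np.arange(1.0, 41.0)
        traces = {}
        for s in samples:
            ct = 20.0 + (12.0 if rng.random() < params.qc_fail_prob else 0.0)
            traces[s] = 1.0 / (1.0 + np.exp(-(cycles - ct) / 1.5))
        _, excluded = hrmsim.hrm_qc_filter(
            traces, cycles, window=params.qc_window
        )
    retained = [s for s in samples if s not in set(excluded)]
    if len(retained) < 2:
        return [], excluded

    curves = []
    for s in retained:
        species = hrmsim.sample_duplexes(
            genotypes[s],
            amplicons,
            mismatch_penalty=params.mismatch_penalty,
            width=params.width,
            salt_offset=params.salt_offset,
        )
        curves.append(
            hrmsim.simulate_melt_curve(
                species,
                noise_sd=params.noise_sd,
                seed=int(rng.integers(2**31)),
                sample_id=s,
            )
        )
    _, diffs = hrmsim.normalize_and_difference(curves, reference=retained[0])
    calls = hrmsim.cluster_genotypes(diffs, threshold=params.cluster_threshold)
    return calls, excluded


def run_pipeline(config: RunConfig, out_dir: Path | str) -> Path:
    """Run all stages and write the outputs listed in the module docstring.

    A partial-stage failure still writes ``manifest.json`` naming the failing
    stage, then re-raises.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    manifest_path = out / "manifest.json"

    def _manifest(status: str) -> None:
        simpanel.write_manifest(
            manifest_path,
            status=status,
            stages=stages,
            config=config.to_dict(),
            seed=config.seed,
            version=__version__,
        )

    stage = "simulate"
    try:
        loci = simpanel.simulate_progenitors(config.sim)
        panel = simpanel.simulate_tetraploid_panel(loci, config.sim)
        simpanel.write_progenitor_fasta(panel.loci, out / "progenitors.fasta")
        simpanel.write_panel_fasta(panel, out / "panel.fasta")
        simpanel.truth_to_table(panel.loci).to_csv(
            out / "truth.tsv", sep="\t", index=False
        )
        stages[stage] = "ok"

        stage = "observe"
        prog_a, prog_b, var_obs = build_observations(panel)
        all_obs = list(prog_a.values()) + list(prog_b.values())
        for per_locus in var_obs.values():
            all_obs.extend(per_locus.values())
        ampliconobs.observations_to_table(all_obs).to_csv(
            out / "observations.tsv", sep="\t", index=False
        )
        stages[stage] = "ok"

        stage = "classify"
        _comps, sites, comp_table = classify_panel(panel)
        comp_table.to_csv(out / "composition.tsv", sep="\t", index=False)
        classify.sites_to_table(sites).to_csv(
            out / "variants.tsv", sep="\t", index=False
        )
        (out / "recovery.json").write_text(
            json.dumps(score_recovery(panel, sites), indent=2) + "\n"
        )
        stages[stage] = "ok"

        stage = "hrm"
        calls_matrix = _marker_calls_from_sites(sites, panel.variety_ids)
        loci_by_id = {l.locus_id: l for l in panel.loci}
        sites_by_marker = {
            f"{s.locus_id}:{s.position}": s for s in sites if s.category == "SNP"
        }
        hrm_rows = []
        hrm_excluded: dict[str, set[str]] = {}
        for m_idx, marker_id in enumerate(calls_matrix.index):
            site = sites_by_marker[marker_id]
            locus = loci_by_id[site.locus_id]
            amplicons = _hrm_amplicon(locus, site, config.hrm.amplicon_length)
            if amplicons is None:
                continue
            major, minor = sorted(
                site.alleles,
                key=lambda a: -sum(1 for c in site.calls.values() if c == a),
            )
            genotypes = {
                v: ((major, minor) if site.calls.get(v) == minor else (major, major))
                for v in panel.variety_ids
            }
            calls, excluded = hrm_genotype_panel(
                genotypes, amplicons, config.hrm, seed=config.seed + 1000 + m_idx
            )
            hrm_excluded[marker_id] = set(excluded)
            for call in calls:
                hrm_rows.append(
                    {
                        "marker": marker_id,
                        "sample": call.sample_id,
                        "cluster": call.cluster_id,
                        "max_abs_diff": round(call.reference_distance, 3),
                    }
                )
            for s in excluded:
                hrm_rows.append(
                    {"marker": marker_id, "sample": s, "cluster": "NA",
                     "max_abs_diff": ""}
                )
        pd.DataFrame(
            hrm_rows, columns=["marker", "sample", "cluster", "max_abs_diff"]
        ).to_csv(out / "hrm_calls.tsv", sep="\t", index=False)
        stages[stage] = "ok"

        stage = "stats"
        marker_rows = []
        for marker_id in calls_matrix.index:
            site = sites_by_marker[marker_id]
            # varieties excluded by the HRM amplification QC become missing
            # calls: counts then sum below the panel size (GSS-72 pattern)
            excluded = hrm_excluded.get(marker_id, set())
            typed = {
                v: c for v, c in site.calls.items() if v not in excluded
            }
            counts = sorted(
                (sum(1 for c in typed.values() if c == a), a)
                for a in site.alleles
            )
            (c1, a1), (c2, a2) = counts
            marker_rows.append(
                {
                    "marker": marker_id,
                    "group": loci_by_id[site.locus_id].source_class,
                    "variant_class": site.collapsed_class,
                    "count1": c2,  # major first, mirroring allele-1 convention
                    "count2": c1,
                }
            )
        if marker_rows:
            marker_table = pd.DataFrame(marker_rows)
            report, summary = markerstats.summarize_markers(
                marker_table, panel_size=config.sim.n_varieties
            )
            report.to_csv(out / "markers.tsv", sep="\t", index=False)
            (out / "marker_summary.json").write_text(
                summary.to_json(indent=2) + "\n"
            )
        else:
            pd.DataFrame(
                columns=["marker", "group", "variant_class", "count1", "count2"]
            ).to_csv(out / "markers.tsv", sep="\t", index=False)
        stages[stage] = "ok"

        stage = "ril"
        seg_rows = []
        if len(calls_matrix.index) > 0:
            markers = list(calls_matrix.index)
            parents = None
            for i, v1 in enumerate(panel.variety_ids):
                for v2 in panel.variety_ids[i + 1 :]:
                    if any(
                        calls_matrix.loc[m, v1] != calls_matrix.loc[m, v2]
                        for m in markers
                    ):
                        parents = (v1, v2)
                        break
                if parents:
                    break
            if parents:
                # only markers that actually segregate between the parents
                markers = [
                    m
                    for m in markers
                    if calls_matrix.loc[m, parents[0]]
                    != calls_matrix.loc[m, parents[1]]
                ]
                p1 = [calls_matrix.loc[m, parents[0]] for m in markers]
                p2 = [calls_matrix.loc[m, parents[1]] for m in markers]
                ril_cfg = dataclasses.replace(
                    config.ril, n_markers=len(markers)
                )
                ril = simpanel.simulate_ril(p1, p2, ril_cfg)
                for m, marker_id in zip(ril.index, markers):
                    row = ril.loc[m]
                    n_a = int((row == "a").sum())
                    n_b = int((row == "b").sum())
                    if n_a + n_b == 0:
                        continue
                    test = markerstats.chi_square_1to1((n_a, n_b), marker_id=marker_id)
                    seg_rows.append(
                        {
                            "marker": marker_id,
                            "n_parent1": n_a,
                            "n_parent2": n_b,
                            "chi2": round(test.chi2, 4),
                            "p": round(test.p, 6),
                            "distorted": test.distorted,
                        }
                    )
        pd.DataFrame(
            seg_rows,
            columns=["marker", "n_parent1", "n_parent2", "chi2", "p", "distorted"],
        ).to_csv(out / "segregation.tsv", sep="\t", index=False)
        stages[stage] = "ok"
    except Exception:
        stages[stage] = "failed"
        _manifest("failed")
        raise

    _manifest("ok")
    return out


def pic_report(
    table: pd.DataFrame, panel_size: int = 96
) -> pd.DataFrame:
    """Append computed PIC (3 decimals) to a marker-count table, plus a match
    flag against an optional expected-PIC column.

    Requires columns ``marker``, ``count1``, ``count2``; rows whose counts sum
    above the panel size are rejected with their line number.
    """
    required = {"marker", "count1", "count2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"marker table is missing columns: {sorted(missing)}")
    expected_col = next(
        (c for c in ("pic_published", "expected", "pic_expected") if c in table.columns),
        None,
    )
    rows = []
    for i, r in enumerate(table.itertuples(), start=2):  # header = line 1
        try:
            c1, c2 = int(r.count1), int(r.count2)
            stats = markerstats.pic((c1, c2), panel_size, str(r.marker))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {i}: {exc}") from exc
        row = {
            "marker": r.marker,
            "count1": c1,
            "count2": c2,
            "pic": stats.pic_rounded,
        }
        if expected_col is not None:
            expect = float(getattr(r, expected_col))
            row["expected"] = expect
            row["match"] = abs(stats.pic_rounded - expect) < 5e-4
        rows.append(row)
    return pd.DataFrame(rows)
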