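"""End-to-end orchestration, statistics wrappers, and reporting.

``run_pipeline`` wires the stages together on synthetic inputs: generate an
unbiased-style bouton sample for each family, fit mixtures with BIC
selection, estimate Monte Carlo cutoffs, classify the boutons, generate and
annotate a segment dataset, mine association rules per cell class and build
the confidence networks, then write every artifact with a manifest so a
rerun under the same configuration and seed is bit-identical.

``nonparametric_tests`` wraps the standard scipy routines (Mann-Whitney U,
Kruskal-Wallis with Dunn's post-hoc comparisons, D'Agostino-Pearson
normality); Dunn's rank z-tests with tie correction and Bonferroni
adjustment are computed here directly.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .association import build_network, build_transactions, lift_matrix, mine_rules
from .classify import classify_boutons, composition_summary
from .cutoffs import mc_cutoffs
from .errors import ConfigurationError
from .mixture import select_by_bic
from .morphometry import annotate_segments
from .specs import DEFAULT_DNM_N, DEFAULT_LM_N, calibrate_default_mixtures
from .synthetic import SegmentGenConfig, generate_bouton_population, generate_segment_dataset


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of a full synthetic-data pipeline run."""

    seed: int = 0
    lm_n: int = DEFAULT_LM_N
    dnm_n: int = DEFAULT_DNM_N
    k_max: int = 9
    mc_iterations: int = 10_000
    mc_multiplier: int = 5
    n_segments: dict = field(
        default_factory=lambda: {"X_like": 43, "Y_like": 37, "interneuron": 7}
    )
    epsilon: float = 0.9
    filter_threshold: float = 0.025
    min_terminals: int = 40
    network_min_support: float = 0.1
    outdir: str = "boutonsort_results"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns the result bundle.

    All artifacts are written under ``cfg.outdir``; the manifest records the
    configuration hash, seeds and package version.  Stage failures propagate
    with the failing stage named; artifacts written before the failure are
    retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)]
    bundle: dict = {"config": cfg.to_dict()}
    stage = "generate"
    try:
        lm_spec, dnm_spec = calibrate_default_mixtures()
        lm_pop = generate_bouton_population(lm_spec, cfg.lm_n, seed=seeds[0])
        dnm_pop = generate_bouton_population(
            dnm_spec, cfg.dnm_n, seed=seeds[1], id_offset=cfg.lm_n
        )
        uts = pd.concat([lm_pop, dnm_pop], ignore_index=True)
        uts.to_csv(out / "uts_boutons.csv", index=False)
        bundle["uts"] = uts

        stage = "fit"
        fits = {}
        for fam, pop in (("LM", lm_pop), ("DNM", dnm_pop)):
            fit, table = select_by_bic(
                pop["volume_um3"].to_numpy(), k_max=cfg.k_max, seed=seeds[2]
            )
            fits[fam] = {"fit": fit, "bic_table": table}
            table.to_csv(out / f"bic_table_{fam}.csv", index=False)
            with open(out / f"fit_{fam}.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=2)
        bundle["fits"] = fits

        stage = "cutoffs"
        cuts = {}
        for fam in ("LM", "DNM"):
            cuts[fam] = mc_cutoffs(
                fits[fam]["fit"],
                R=cfg.mc_iterations,
                multiplier=cfg.mc_multiplier,
                seed=seeds[3],
                family=fam,
            )
        with open(out / "cutoffs.json", "w") as fh:
            json.dump({f: c.to_dict() for f, c in cuts.items()}, fh, indent=2)
        bundle["cutoffs"] = cuts

        stage = "classify"
        labeled = classify_boutons(uts, cuts["LM"], cuts["DNM"])
        labeled.to_csv(out / "uts_labeled.csv", index=False)
        comp = composition_summary(labeled)
        comp.to_csv(out / "composition_uts.csv", index=False)
        bundle["labeled"] = labeled
        bundle["composition"] = comp

        stage = "segments"
        seg_cfg = SegmentGenConfig(
            n_segments=cfg.n_segments, epsilon=cfg.epsilon, seed=seeds[4]
        )
        segments, seg_boutons = generate_segment_dataset(seg_cfg, lm_spec, dnm_spec)
        segments = annotate_segments(segments)
        seg_boutons = classify_boutons(seg_boutons, cuts["LM"], cuts["DNM"])
        segments.to_csv(out / "segments.csv", index=False)
        seg_boutons.to_csv(out / "segment_boutons.csv", index=False)
        bundle["segments"] = segments
        bundle["segment_boutons"] = seg_boutons

        stage = "association"
        rules_by_class, networks = {}, {}
        class_of_segment = segments.set_index("segment_id")["cell_class"]
        for cls in ("X_like", "Y_like"):
            seg_ids = class_of_segment[class_of_segment == cls].index
            sub = seg_boutons[seg_boutons["segment_id"].isin(seg_ids)]
            if sub.empty:
                continue
            tx = build_transactions(
                sub,
                filter_threshold=cfg.filter_threshold,
                min_terminals=cfg.min_terminals,
            )
            rules = mine_rules(tx)
            rules.to_csv(out / f"rules_{cls}.csv", index=False)
            lift_matrix(rules).to_csv(out / f"lift_matrix_{cls}.csv")
            net = build_network(rules, min_support=cfg.network_min_support)
            with open(out / f"network_{cls}.json", "w") as fh:
                json.dump(
                    {
                        "nodes": list(net.graph.nodes),
                        "edges": [
                            {"from": u, "to": v, "confidence": d["weight"]}
                            for u, v, d in net.graph.edges(data=True)
                        ],
                        "outstrength": net.outstrength,
                    },
                    fh,
                    indent=2,
                )
            rules_by_class[cls] = rules
            networks[cls] = net
        bundle["rules"] = rules_by_class
        bundle["networks"] = networks
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stage_seeds": seeds,
        "counts": {
            "uts_boutons": int(len(uts)),
            "segments": int(len(segments)),
            "segment_boutons": int(len(seg_boutons)),
        },
        "selected_k": {f: int(fits[f]["fit"].k) for f in fits},
        "cutoffs": {f: [float(b) for b in cuts[f].boundaries] for f in cuts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    write_report(bundle, out)
    return bundle


# ---------------------------------------------------------------------------
# Nonparametric statistics wrappers
# ---------------------------------------------------------------------------


def _dunn_posthoc(samples: dict) -> pd.DataFrame:
    """Dunn's rank z-tests after Kruskal-Wallis, Bonferroni-adjusted."""
    names = list(samples)
    all_vals = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    ranks = stats.rankdata(all_vals)
    n_total = all_vals.size
    mean_rank, sizes, start = {}, {}, 0
    for g in names:
        n_g = len(samples[g])
        mean_rank[g] = ranks[start : start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p, min(1.0, p * m)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "p_value", "p_adjusted"]
    )


def nonparametric_tests(samples, test: str) -> pd.DataFrame:
    """Standard nonparametric comparisons on a dict of named samples.

    ``test`` is one of ``mann_whitney`` (exactly two samples),
    ``kruskal_wallis_dunn`` (two or more; omnibus plus Dunn's adjusted
    pairwise table) or ``dagostino_pearson`` (normality per sample, n >= 8).
    """
    if not isinstance(samples, dict):
        raise ConfigurationError("samples must be a dict of name -> values")
    sizes = {g: len(v) for g, v in samples.items()}
    if test == "mann_whitney":
        if len(samples) != 2:
            raise ConfigurationError("Mann-Whitney requires exactly two samples")
        if min(sizes.values()) < 2:
            raise ConfigurationError("need >= 2 observations per sample")
        (na, a), (nb, b) = samples.items()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return pd.DataFrame(
            [("mann_whitney", f"{na} vs {nb}", stat, p)],
            columns=["test", "comparison", "statistic", "p_value"],
        )
    if test == "kruskal_wallis_dunn":
        if len(samples) < 2 or min(sizes.values()) < 2:
            raise ConfigurationError("need >= 2 samples with >= 2 observations each")
        stat, p = stats.kruskal(*samples.values())
        omnibus = pd.DataFrame(
            [("kruskal_wallis", "omnibus", stat, p, p)],
            columns=["test", "comparison", "statistic", "p_value", "p_adjusted"],
        )
        dunn = _dunn_posthoc(samples)
        dunn.insert(0, "test", "dunn")
        dunn["comparison"] = dunn["group_a"] + " vs " + dunn["group_b"]
        dunn = dunn[["test", "comparison", "statistic", "p_value", "p_adjusted"]]
        return pd.concat([omnibus, dunn], ignore_index=True)
    if test == "dagostino_pearson":
        if min(sizes.values()) < 8:
            raise ConfigurationError("normality test requires n >= 8 per sample")
        rows = [
            ("dagostino_pearson", g, *stats.normaltest(v)) for g, v in samples.items()
        ]
        return pd.DataFrame(
            rows, columns=["test", "comparison", "statistic", "p_value"]
        )
    raise ConfigurationError(f"unknown test {test!r}")


def write_report(bundle: dict, outdir) -> Path:
    """Write a human-readable markdown summary of a pipeline bundle."""
    out = Path(outdir)
    lines = ["# boutonsort pipeline report", ""]
    man = bundle.get("manifest", {})
    if man:
        lines += [
            f"- package version: {man['package_version']}",
            f"- config hash: `{man['config_hash']}`",
            f"- selected components: {man['selected_k']}",
            "",
        ]
    comp = bundle.get("composition")
    if comp is not None and not comp.empty:
        lines += ["## Composition (percent per subpopulation)", ""]
        lines.append(comp.to_string(index=False))
        lines.append("")
    cuts = bundle.get("cutoffs", {})
    for fam, c in cuts.items():
        b = ", ".join(f"{x:.3f}" for x in c.boundaries)
        lines.append(f"- {fam} cutoffs (um^3): {b}")
    lines.append("")
    rules = bundle.get("rules", {})
    if not rules or all(r.empty for r in rules.values()):
        lines.append("No associations: the rule table is empty.")
    else:
        for cls, r in rules.items():
            lines += [f"## Association rules ({cls})", "", r.to_string(index=False), ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
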