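"""Generative simulator of the biased-multinomial MGS measurement model.

The model: each taxon's analytical response in a sample is its actual
abundance times a taxon-specific bias factor (aggregating extraction, PCR,
sequencing and bioinformatic biases into one term, as is appropriate for a
locked-down protocol); sequencing saturates the responses to a fixed read
budget, so expected relative abundances are

    E[RA_z] = A_z * B_z / sum_t (A_t * B_t)

and observed counts are a multinomial draw of the per-sample depth over
these expected proportions.  ``noise="expectation"`` skips the draw and
returns ``depth * E[RA]`` exactly — useful for algebraic identities that
hold without sampling noise.

Three scenario builders reproduce the framework's validation designs:

* ``mock_community`` — many mock communities assembled from a small strain
  panel, each member diluted from stock by a specified factor (the known
  actual abundance).
* ``spikein_backgrounds`` — diverse stool-like backgrounds sharing four
  spike-in taxa at fixed concentrations spanning two orders of magnitude
  plus the internal standard, with technical replicates per background.
* ``dilution_series`` — one community diluted to a range of fractions with
  the internal standard added at constant concentration after dilution.

Biases are lognormal by default (median 1, configurable sigma) to span the
regime where biases vary substantially and unpredictably between taxa;
explicit per-taxon bias vectors are always accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .tables import CountTable, InternalStandardSpec, SampleMetadata, SpikeTruth

__all__ = [
    "CommunityDesign",
    "BiasModel",
    "SequencingModel",
    "ScenarioSpec",
    "TruthBundle",
    "simulate_counts",
    "simulate_scenario",
    "scenario_mock_community",
    "scenario_spikein_backgrounds",
    "scenario_dilution_series",
]

# Defaults shared by the stool-like scenarios.  Spike and IS concentrations
# are the validated reference values (copies/mcL); the native background
# total is set so the lowest spike sits near relative abundance 5e-4, the
# low end observed for spiked taxa in real stool.
DEFAULT_SPIKE_ABUNDANCES: Mapping[str, float] = {
    "A_baumannii": 4.8e4,
    "V_furnissii": 9.6e3,
    "N_meningitidis": 5.4e3,
    "A_hydrophila": 6.2e2,
}
DEFAULT_IS_TAXON = "L_pneumophila"
DEFAULT_IS_ABUNDANCE = 2.16e5
DEFAULT_NATIVE_TOTAL = 1.2e6
DEFAULT_N_NATIVE = 50
DEFAULT_BIAS_SIGMA = 1.0
DEFAULT_MOCK_DILUTIONS = (1 / 2, 1 / 3, 1 / 7)
DEFAULT_SERIES_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class CommunityDesign:
    """Per-sample taxon actual abundances (the simulator's ground truth)."""

    abundances: pd.DataFrame  # samples x taxa, >= 0
    units: str = "copies/mcL"

    def __post_init__(self) -> None:
        df = self.abundances.astype(float)
        if (df.to_numpy() < 0).any():
            raise ValidationError("actual abundances must be nonnegative")
        empty = df.sum(axis=1) == 0
        if empty.any():
            raise ValidationError(
                f"sample {df.index[empty][0]!r} has no taxon with abundance > 0"
            )
        self.abundances = df

    @property
    def sample_ids(self) -> list:
        return list(self.abundances.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.abundances.columns)


@dataclass
class BiasModel:
    """Per-taxon multiplicative bias factors (all positive)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        s = self.factors.astype(float)
        if (s <= 0).any():
            raise ValidationError("bias factors must be positive")
        self.factors = s

    @classmethod
    def lognormal(
        cls,
        taxon_ids: Sequence[str],
        sigma: float = DEFAULT_BIAS_SIGMA,
        rng: Optional[np.random.Generator] = None,
        seed: Optional[int] = None,
    ) -> "BiasModel":
        """Mean-1 lognormal biases with the given log-scale sigma.

        Only bias *ratios* are identifiable, so the overall scale is a
        convention; normalising the ensemble mean to 1 keeps the
        bias-weighted total response on the same scale as the total actual
        abundance, which keeps depth/abundance calibrations meaningful.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        draws = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(taxon_ids)))
        return cls(pd.Series(draws, index=list(taxon_ids)))

    @classmethod
    def uniform(cls, taxon_ids: Sequence[str]) -> "BiasModel":
        return cls(pd.Series(1.0, index=list(taxon_ids)))


@dataclass
class SequencingModel:
    """Read-budget model: per-sample depth and noise mode.

    ``noise``: ``"multinomial"`` draws counts from a multinomial over the
    expected relative abundances; ``"expectation"`` returns the exact
    expected counts.  ``depth_distribution="poisson"`` draws each sample's
    depth from a Poisson around the mean depth.
    """

    depth: int = 100_000
    noise: str = "multinomial"
    depth_distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.noise not in ("expectation", "multinomial"):
            raise ValidationError(f"unknown noise mode {self.noise!r}")
        if self.depth_distribution not in ("fixed", "poisson"):
            raise ValidationError(
                f"unknown depth distribution {self.depth_distribution!r}"
            )


@dataclass
class TruthBundle:
    """Everything a test harness needs to check recovery against."""

    design: CommunityDesign
    bias: BiasModel
    expected_ra: pd.DataFrame
    is_spec: Optional[InternalStandardSpec] = None
    spike_truth: Optional[SpikeTruth] = None
    metadata: Optional[SampleMetadata] = None

    def bias_ratio(self, taxon_id: str) -> float:
        """Generator bias ratio B_taxon / B_IS (needs an internal standard)."""
        if self.is_spec is None:
            raise ValidationError("no internal standard in this truth bundle")
        return float(
            self.bias.factors[taxon_id] / self.bias.factors[self.is_spec.taxon_id]
        )


def simulate_counts(
    design: CommunityDesign,
    bias: BiasModel,
    seq: SequencingModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CountTable, TruthBundle]:
    """Simulate a count table from actual abundances, biases and a read budget.

    Expected relative abundances are the bias-weighted abundances closed to
    one per sample.  In multinomial mode a seed (or generator) must be
    supplied; counts in each sample sum exactly to the sample's depth.
    """
    taxa = design.taxon_ids
    if set(taxa) != set(bias.factors.index):
        raise ValidationError("design and bias model list different taxa")
    b = bias.factors.reindex(taxa).to_numpy()
    a = design.abundances.to_numpy()
    response = a * b[None, :]
    totals = response.sum(axis=1)
    if (totals <= 0).any():
        bad = design.sample_ids[int(np.argmax(totals <= 0))]
        raise ValidationError(f"sample {bad!r} has zero total analytical response")
    expected = response / totals[:, None]
    expected_df = pd.DataFrame(
        expected, index=design.abundances.index, columns=taxa
    )

    if seq.noise == "expectation":
        counts = expected * float(seq.depth)
    else:
        if rng is None:
            if seed is None:
                raise ValidationError("multinomial mode requires a seed or rng")
            rng = np.random.default_rng(seed)
        n_samples = expected.shape[0]
        if seq.depth_distribution == "poisson":
            depths = rng.poisson(seq.depth, size=n_samples)
            depths = np.maximum(depths, 1)
        else:
            depths = np.full(n_samples, seq.depth)
        counts = np.empty_like(expected)
        for i in range(n_samples):
            counts[i] = rng.multinomial(int(depths[i]), expected[i])

    table = CountTable(
        pd.DataFrame(counts, index=design.abundances.index, columns=taxa),
        mode="counts",
    )
    return table, TruthBundle(design=design, bias=bias, expected_ra=expected_df)


@dataclass
class ScenarioSpec:
    """Declarative description of one simulation scenario.

    ``kind`` selects the builder (``mock_community``, ``spikein_backgrounds``
    or ``dilution_series``); ``params`` holds the kind-specific knobs; the
    seed drives every random choice so identical specs yield bit-identical
    tables.  Round-trips through YAML.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    KINDS = ("mock_community", "spikein_backgrounds", "dilution_series")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown scenario kind {self.kind!r}")

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(
            yaml.safe_dump(
                {"kind": self.kind, "seed": int(self.seed), "params": self.params},
                sort_keys=False,
            )
        )
        return path

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "kind" not in raw:
            raise ValidationError(f"{path}: not a scenario spec")
        return cls(
            kind=raw["kind"], params=raw.get("params", {}), seed=int(raw.get("seed", 0))
        )


def scenario_mock_community(
    n_communities: int = 80,
    *,
    n_taxa: int = 7,
    subset_rule: str = "random",
    min_subset: int = 2,
    dilution_levels: Sequence[float] = DEFAULT_MOCK_DILUTIONS,
    bias_sigma: float = DEFAULT_BIAS_SIGMA,
    depth: int = 100_000,
    noise: str = "multinomial",
    seed: int = 0,
) -> ScenarioSpec:
    """Mock communities assembled from a strain panel at stock dilutions.

    Each community contains a random subset (>= ``min_subset``) of the
    panel, every member at an abundance drawn from ``dilution_levels``
    (the dilution from overnight stock doubles as the known actual
    abundance).  ``subset_rule="all"`` puts every strain in every community.
    """
    if min_subset < 2:
        raise ValidationError("communities need >= 2 member taxa")
    if subset_rule not in ("random", "all"):
        raise ValidationError(f"unknown subset_rule {subset_rule!r}")
    if any(d <= 0 for d in dilution_levels):
        raise ValidationError("dilution levels must be positive")
    return ScenarioSpec(
        kind="mock_community",
        seed=seed,
        params={
            "n_communities": int(n_communities),
            "n_taxa": int(n_taxa),
            "subset_rule": subset_rule,
            "min_subset": int(min_subset),
            "dilution_levels": [float(d) for d in dilution_levels],
            "bias_sigma": float(bias_sigma),
            "depth": int(depth),
            "noise": noise,
        },
    )


def scenario_spikein_backgrounds(
    n_backgrounds: int = 5,
    n_replicates: int = 3,
    *,
    spike_abundances: Optional[Mapping[str, float]] = None,
    is_taxon: str = DEFAULT_IS_TAXON,
    is_abundance: float = DEFAULT_IS_ABUNDANCE,
    n_native_taxa: int = DEFAULT_N_NATIVE,
    native_total: float = DEFAULT_NATIVE_TOTAL,
    native_total_sigma: float = 0.7,
    dirichlet_alpha: float = 1.0,
    bias_sigma: float = DEFAULT_BIAS_SIGMA,
    depth: int = 100_000,
    noise: str = "multinomial",
    seed: int = 0,
) -> ScenarioSpec:
    """Diverse stool-like backgrounds sharing fixed spikes and the IS.

    Native compositions are Dirichlet draws scaled to a per-background
    total microbial load (median ``native_total``, lognormal spread
    ``native_total_sigma`` — distinct donors carry very different loads,
    which is what makes spike relative abundances vary wildly between
    backgrounds even though the spikes are constant).  Compositions are
    distinct across backgrounds and identical across the technical
    replicates within a background; the spike taxa and internal standard
    are constant in every sample.
    """
    spikes = dict(spike_abundances or DEFAULT_SPIKE_ABUNDANCES)
    if any(v <= 0 for v in spikes.values()):
        raise ValidationError("spike abundances must be positive")
    if is_abundance <= 0:
        raise ValidationError("internal standard abundance must be positive")
    return ScenarioSpec(
        kind="spikein_backgrounds",
        seed=seed,
        params={
            "n_backgrounds": int(n_backgrounds),
            "n_replicates": int(n_replicates),
            "spike_abundances": {k: float(v) for k, v in spikes.items()},
            "is_taxon": is_taxon,
            "is_abundance": float(is_abundance),
            "n_native_taxa": int(n_native_taxa),
            "native_total": float(native_total),
            "native_total_sigma": float(native_total_sigma),
            "dirichlet_alpha": float(dirichlet_alpha),
            "bias_sigma": float(bias_sigma),
            "depth": int(depth),
            "noise": noise,
        },
    )


def scenario_dilution_series(
    fractions: Sequence[float] = DEFAULT_SERIES_FRACTIONS,
    *,
    base_community: Optional[Mapping[str, float]] = None,
    is_taxon: str = DEFAULT_IS_TAXON,
    is_abundance: float = DEFAULT_IS_ABUNDANCE,
    n_native_taxa: int = DEFAULT_N_NATIVE,
    native_total: float = DEFAULT_NATIVE_TOTAL,
    abundance_sigma: float = 1.5,
    bias_sigma: float = DEFAULT_BIAS_SIGMA,
    rare_taxon_ra: Optional[float] = None,
    depth: int = 1_000_000,
    noise: str = "multinomial",
    seed: int = 0,
) -> ScenarioSpec:
    """One community diluted to several fractions, IS added post-dilution.

    Native abundances are either given explicitly (``base_community``) or
    drawn lognormally (sigma ``abundance_sigma``) and scaled to
    ``native_total``.  Each sample holds the community scaled by its
    fraction plus the internal standard at constant ``is_abundance``.
    ``rare_taxon_ra`` optionally adds one unit-bias taxon constructed so
    its expected relative abundance in the undiluted sample equals the
    given value — for probing the limit of quantitation.
    """
    fracs = [float(f) for f in fractions]
    if any(f <= 0 or f > 1 for f in fracs):
        raise ValidationError("dilution fractions must lie in (0, 1]")
    if len(fracs) != len(set(fracs)):
        raise ValidationError("dilution fractions must be distinct")
    return ScenarioSpec(
        kind="dilution_series",
        seed=seed,
        params={
            "fractions": fracs,
            "base_community": (
                {k: float(v) for k, v in base_community.items()}
                if base_community
                else None
            ),
            "is_taxon": is_taxon,
            "is_abundance": float(is_abundance),
            "n_native_taxa": int(n_native_taxa),
            "native_total": float(native_total),
            "abundance_sigma": float(abundance_sigma),
            "bias_sigma": float(bias_sigma),
            "rare_taxon_ra": (None if rare_taxon_ra is None else float(rare_taxon_ra)),
            "depth": int(depth),
            "noise": noise,
        },
    )


def _realize_mock_community(p: dict, rng: np.random.Generator):
    if p["min_subset"] < 2:
        raise ValidationError("communities need >= 2 member taxa")
    if any(d <= 0 for d in p["dilution_levels"]):
        raise ValidationError("dilution levels must be positive")
    taxa = [f"strain_{i + 1}" for i in range(p["n_taxa"])]
    levels = np.asarray(p["dilution_levels"], dtype=float)
    rows = []
    ids = []
    for c in range(p["n_communities"]):
        row = np.zeros(len(taxa))
        if p["subset_rule"] == "all":
            members = np.arange(len(taxa))
        else:
            k = int(rng.integers(p["min_subset"], len(taxa) + 1))
            members = rng.choice(len(taxa), size=k, replace=False)
        row[members] = rng.choice(levels, size=len(members))
        rows.append(row)
        ids.append(f"community_{c + 1:03d}")
    design = CommunityDesign(
        pd.DataFrame(rows, index=ids, columns=taxa), units="stock fraction"
    )
    bias = BiasModel.lognormal(taxa, sigma=p["bias_sigma"], rng=rng)
    return design, bias, None, None, None


def _realize_spikein_backgrounds(p: dict, rng: np.random.Generator):
    if any(v <= 0 for v in p["spike_abundances"].values()):
        raise ValidationError("spike abundances must be positive")
    if p["is_abundance"] <= 0:
        raise ValidationError("internal standard abundance must be positive")
    native = [f"native_{i + 1:02d}" for i in range(p["n_native_taxa"])]
    spikes = p["spike_abundances"]
    is_taxon = p["is_taxon"]
    taxa = native + list(spikes) + [is_taxon]

    rows, ids, meta_rows = [], [], []
    for b in range(p["n_backgrounds"]):
        comp = rng.dirichlet(np.full(len(native), p["dirichlet_alpha"]))
        total = p["native_total"] * float(
            np.exp(rng.normal(0.0, p.get("native_total_sigma", 0.7)))
        )
        native_abund = comp * total
        vec = np.concatenate(
            [native_abund, list(spikes.values()), [p["is_abundance"]]]
        )
        for r in range(p["n_replicates"]):
            rows.append(vec.copy())
            sid = f"bg{b + 1}_rep{r + 1}"
            ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "replicate_group": f"bg{b + 1}",
                    "background_id": f"bg{b + 1}",
                    "dilution_fraction": np.nan,
                }
            )
    design = CommunityDesign(pd.DataFrame(rows, index=ids, columns=taxa))
    bias = BiasModel.lognormal(taxa, sigma=p["bias_sigma"], rng=rng)
    is_spec = InternalStandardSpec(is_taxon, p["is_abundance"])
    truth = SpikeTruth.uniform(spikes)
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return design, bias, is_spec, truth, metadata


def _realize_dilution_series(p: dict, rng: np.random.Generator):
    if any(f <= 0 or f > 1 for f in p["fractions"]):
        raise ValidationError("dilution fractions must lie in (0, 1]")
    if p["base_community"]:
        base = pd.Series(p["base_community"], dtype=float)
    else:
        native = [f"native_{i + 1:02d}" for i in range(p["n_native_taxa"])]
        draws = np.exp(rng.normal(0.0, p["abundance_sigma"], size=len(native)))
        base = pd.Series(draws / draws.sum() * p["native_total"], index=native)
    is_taxon = p["is_taxon"]
    taxa = list(base.index) + [is_taxon]
    bias = BiasModel.lognormal(taxa, sigma=p["bias_sigma"], rng=rng)

    if p.get("rare_taxon_ra"):
        # Unit-bias taxon whose expected RA in the undiluted sample equals
        # the requested value: A_r / (A_r + D) = target with D the undiluted
        # bias-weighted total of everything else.
        target = float(p["rare_taxon_ra"])
        d_total = float(
            (base * bias.factors[base.index]).sum()
            + p["is_abundance"] * bias.factors[is_taxon]
        )
        a_rare = target * d_total / (1.0 - target)
        base = pd.concat([base, pd.Series({"rare_taxon": a_rare})])
        taxa = list(base.index) + [is_taxon]
        bias = BiasModel(
            pd.concat(
                [bias.factors.drop(is_taxon), pd.Series({"rare_taxon": 1.0}),
                 bias.factors[[is_taxon]]]
            ).reindex(taxa)
        )

    rows, ids, meta_rows = [], [], []
    for f in p["fractions"]:
        vec = np.concatenate([base.to_numpy() * f, [p["is_abundance"]]])
        sid = f"frac_{f:g}"
        rows.append(vec)
        ids.append(sid)
        meta_rows.append(
            {
                "sample_id": sid,
                "replicate_group": "series",
                "background_id": "base",
                "dilution_fraction": f,
            }
        )
    design = CommunityDesign(pd.DataFrame(rows, index=ids, columns=taxa))
    is_spec = InternalStandardSpec(is_taxon, p["is_abundance"])
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return design, bias, is_spec, None, metadata


_REALIZERS = {
    "mock_community": _realize_mock_community,
    "spikein_backgrounds": _realize_spikein_backgrounds,
    "dilution_series": _realize_dilution_series,
}


def realize_scenario(
    spec: ScenarioSpec,
) -> tuple[CommunityDesign, BiasModel, Optional[InternalStandardSpec],
           Optional[SpikeTruth], Optional[SampleMetadata], SequencingModel,
           np.random.Generator]:
    """Expand a scenario spec into concrete simulation inputs.

    The returned generator has consumed the design/bias draws and is handed
    on to :func:`simulate_counts` so the whole scenario is one deterministic
    stream per seed.
    """
    rng = np.random.default_rng(spec.seed)
    design, bias, is_spec, truth, metadata = _REALIZERS[spec.kind](spec.params, rng)
    seq = SequencingModel(depth=spec.params["depth"], noise=spec.params["noise"])
    return design, bias, is_spec, truth, metadata, seq, rng


def simulate_scenario(spec: ScenarioSpec) -> tuple[CountTable, TruthBundle]:
    """Realize and simulate a scenario in one call."""
    design, bias, is_spec, truth, metadata, seq, rng = realize_scenario(spec)
    table, bundle = simulate_counts(design, bias, seq, rng=rng)
    bundle.is_spec = is_spec
    bundle.spike_truth = truth
    bundle.metadata = metadata
    return table, bundle
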