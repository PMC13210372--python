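"""Reference experiment protocols on the synthetic cohorts.

These functions fix the study conditions used by the test suite, the
acceptance script and the CLI: cohort sizes, train/test splits by infant,
training schedules and statistical tests. They are thin orchestrations of
the library modules; all numbers they report are computed at run time.

Desk-scale problem sizes (chosen to keep every protocol runnable on one
CPU in minutes): the main cohort is 200 infants x 4 episodes at default
noise with an 80/20 infant split; the uncertainty ensemble is 130
complete-modality infants x 4 episodes; the federated study partitions the
main training split over 8 sites and runs 20 rounds of 5 local epochs.

The personalization study models deployment under population shift: the
shared model is trained on a typical-expressivity cohort, meta-trained on
a disjoint strongly heterogeneous cohort (per-infant expressivity SD 3.5 —
the manipulation personalization must recover), and evaluated on 40 fresh
heterogeneous infants with 32 clips each (few-shot support drawn from the
first clips, query from the rest).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .federated import (FedConfig, SiteShard, local_dp_train,
                        partition_non_iid, run_federation)
from .fusion_net import PainFusionModel
from .learning import maml_adapt, predict_levels, train_supervised
from .synthetic_data import ConceptDataset, SynthConfig, concept_dataset

# desk-scale supervised schedule
TRAIN_EPOCHS = 30
TRAIN_LR = 3e-3
# few-shot adaptation protocol: proximally regularized gradient steps on
# the personalization parameters, matching the meta-training inner loop
ADAPT_STEPS = 5
ADAPT_LR = 0.2
ADAPT_PROX = 0.05
# meta-training outer loop (first-order, per-infant tasks)
META_OUTER_LR = 0.005
META_EPOCHS = 5
# heterogeneity manipulation for the personalization study
HETERO_EXPRESSIVITY_SD = 3.5


def split_by_infant(ds: ConceptDataset, test_fraction: float = 0.2,
                    seed: int = 0) -> tuple[ConceptDataset, ConceptDataset]:
    """Held-out split with disjoint infant ids."""
    infants = np.unique(ds.infant_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(infants)
    n_test = max(1, int(round(test_fraction * len(infants))))
    test_ids = set(infants[:n_test])
    mask = np.isin(ds.infant_ids, list(test_ids))
    return ds.subset(~mask), ds.subset(mask)


def concept_macro_f1(ds: ConceptDataset) -> float:
    """Macro-F1 of rule-based concept firing against clean-signal truth,
    over concepts with at least one labeled positive or prediction."""
    f1s = []
    for k in range(12):
        m = ds.gt_available[:, k]
        tp = np.sum(ds.fired[m, k] & ds.gt_fired[m, k])
        fp = np.sum(ds.fired[m, k] & ~ds.gt_fired[m, k])
        fn = np.sum(~ds.fired[m, k] & ds.gt_fired[m, k])
        if tp + fp + fn == 0:
            f1s.append(1.0)       # concept never fires and never should
        else:
            f1s.append(2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s))


def train_main_model(train_ds: ConceptDataset, seed: int = 0,
                     epochs: int = TRAIN_EPOCHS) -> PainFusionModel:
    model = PainFusionModel(seed=seed)
    train_supervised(model, train_ds.activations, train_ds.available,
                     train_ds.pain, epochs=epochs, lr=TRAIN_LR, seed=seed + 1)
    return model


def main_cohort_experiment(seed: int, n_infants: int = 200) -> dict:
    """Cohort generation, concept recovery and end-to-end accuracy."""
    ds = concept_dataset(SynthConfig(n_infants=n_infants, seed=seed))
    train_ds, test_ds = split_by_infant(ds, seed=seed)
    model = train_main_model(train_ds, seed=seed)
    pred = predict_levels(model, test_ds.activations, test_ds.available)
    return {
        "dataset": ds, "train": train_ds, "test": test_ds, "model": model,
        "concept_macro_f1": concept_macro_f1(ds),
        "holdout_accuracy": float(np.mean(pred == test_ds.pain)),
        "predictions": pred,
    }


def masked_uncertainty_experiment(model: PainFusionModel, seed: int,
                                  n_infants: int = 130) -> dict:
    """Mean evidential uncertainty with one modality masked vs complete
    inputs on a complete-modality ensemble (paired one-sided test)."""
    cfg = SynthConfig(n_infants=n_infants, seed=seed + 101,
                      modality_proportions=(1.0, 0.0, 0.0),
                      ventilated_fraction=0.0)
    ens = concept_dataset(cfg)
    out_c = model.forward(ens.activations, ens.available)
    masked = ens.available.copy()
    masked[:, 4:8] = False            # audio-derived concepts C5-C8
    out_m = model.forward(ens.activations, masked)
    u_c = 4.0 / out_c["alpha"].numpy().sum(axis=1)
    u_m = 4.0 / out_m["alpha"].numpy().sum(axis=1)
    t, p = stats.ttest_rel(u_m, u_c, alternative="greater")
    return {"n": len(ens), "mean_u_complete": float(u_c.mean()),
            "mean_u_masked": float(u_m.mean()), "t": float(t),
            "p_value": float(p)}


def personalization_experiment(seed: int, n_eval_infants: int = 40,
                               shots: tuple = (5, 20)) -> dict:
    """Few-shot personalization uplift under per-infant expressivity shift.

    The base model is supervised on a typical-expressivity cohort, then
    meta-trained (first-order outer loop on per-infant support/query tasks
    from a disjoint heterogeneous cohort) so that the few-shot inner update
    is effective. Evaluation infants come from a third, disjoint
    heterogeneous cohort: for each infant the query accuracy after adapting
    on the first ``k`` support clips is compared to the unadapted accuracy
    (paired t-test over infants).
    """
    from .learning import MetaTask, meta_train

    tr = concept_dataset(SynthConfig(n_infants=60, seed=seed + 201))
    mt = concept_dataset(SynthConfig(
        n_infants=40, episodes_per_infant=12, seed=seed + 203,
        expressivity_sd=HETERO_EXPRESSIVITY_SD))
    ev = concept_dataset(SynthConfig(
        n_infants=n_eval_infants, episodes_per_infant=32, seed=seed + 202,
        expressivity_sd=HETERO_EXPRESSIVITY_SD))
    model = train_main_model(tr, seed=seed)

    def _block(sub, lo, hi, tag):
        idx = np.arange(lo, hi)
        return {"activations": sub.activations[idx],
                "available": sub.available[idx], "pain": sub.pain[idx],
                "clip_ids": [f"{tag}{i}" for i in idx]}

    tasks = [MetaTask(iid,
                      _block(mt.subset(mt.infant_ids == iid), 0, 5, "s"),
                      _block(mt.subset(mt.infant_ids == iid), 5, 12, "q"))
             for iid in np.unique(mt.infant_ids)]
    meta_train(model, tasks, outer_lr=META_OUTER_LR, inner_lr=ADAPT_LR,
               steps=ADAPT_STEPS, epochs=META_EPOCHS,
               eval_infant_ids=set(np.unique(ev.infant_ids)))
    results: dict = {"n_infants": n_eval_infants}
    for k in shots:
        uplifts = []
        for iid in np.unique(ev.infant_ids):
            sub = ev.subset(ev.infant_ids == iid)
            support = {f: getattr(sub, f)[:k]
                       for f in ("activations", "available", "pain")}
            query = {f: getattr(sub, f)[20:]
                     for f in ("activations", "available", "pain")}
            base_acc = np.mean(predict_levels(
                model, query["activations"], query["available"]) == query["pain"])
            adapted = maml_adapt(model, support, inner_lr=ADAPT_LR,
                                 steps=ADAPT_STEPS, prox_weight=ADAPT_PROX)
            ad_acc = np.mean(predict_levels(
                adapted, query["activations"], query["available"]) == query["pain"])
            uplifts.append(ad_acc - base_acc)
        uplifts = np.array(uplifts)
        t, p = stats.ttest_1samp(uplifts, 0.0, alternative="greater")
        results[f"uplift_{k}shot"] = float(uplifts.mean())
        results[f"p_value_{k}shot"] = float(p)
    return results


def federated_experiment(train_ds: ConceptDataset, test_ds: ConceptDataset,
                         seed: int, rounds: int = 20,
                         local_epochs: int = 5) -> dict:
    """Noise-free federated training vs the same SGD on pooled data."""
    cfg = FedConfig(rounds=rounds, local_epochs=local_epochs)
    shards = partition_non_iid(train_ds, cfg, seed=seed + 301)
    val = {"activations": test_ds.activations,
           "available": test_ds.available, "pain": test_ds.pain}
    _, account, history = run_federation(shards, cfg, seed=seed + 302,
                                         val_data=val, sigma=0.0)
    fed_acc = max(h["val_accuracy"] for h in history)
    pooled = SiteShard(
        "pooled",
        np.concatenate([s.activations for s in shards]),
        np.concatenate([s.available for s in shards]),
        np.concatenate([s.pain for s in shards]),
        np.concatenate([s.pain_true for s in shards]),
        float(np.mean(np.concatenate([s.pain_true for s in shards]) >= 2)),
        True, 0.0)
    central = PainFusionModel(seed=0)
    state, _ = local_dp_train(central.state_dict(), pooled, cfg, 0.0,
                              np.random.default_rng(seed + 303), epochs=20)
    central.load_state_dict(state)
    cen_pred = predict_levels(central, test_ds.activations, test_ds.available)
    cen_acc = float(np.mean(cen_pred == test_ds.pain))
    return {"federated_accuracy": float(fed_acc),
            "centralized_accuracy": cen_acc,
            "gap": cen_acc - float(fed_acc),
            "rounds_run": len(history),
            "shard_sizes": [len(s) for s in shards],
            "pain_ratios": [s.pain_event_ratio for s in shards]}
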