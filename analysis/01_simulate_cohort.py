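"""Generate the synthetic study materials.

Writes the plasma cohort (35 patients in four planted metabolic
phenotypes + 20 healthy controls, 51-metabolite panel, ~1% missing),
the ground-truth labels, the toy endothelial network, the activity
catalogue and the metabolite->transport mapping.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import yaml

from endoflux import synthdata
from endoflux.activities import write_catalogue
from endoflux.metabolomics import write_table
from endoflux.netcore import write_network_json


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--dir", type=str, default="results")
    args = ap.parse_args()
    out = Path(args.dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = synthdata.CohortConfig(seed=args.seed)
    table, truth = synthdata.simulate_cohort(cfg)
    net = synthdata.make_toy_network()

    write_table(table, out / "cohort.csv")
    truth.labels.rename_axis("sample_id").to_csv(out / "truth.csv")
    write_network_json(net, out / "network.json")
    write_catalogue(synthdata.toy_activity_catalogue(), out / "catalogue.json")
    synthdata.toy_transport_mapping().to_csv(out / "mapping.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)

    n_missing = int(table.values.isna().to_numpy().sum())
    print(f"cohort: {table.values.shape[0]} samples x {table.values.shape[1]} "
          f"metabolites, {n_missing} missing cells "
          f"({100 * table.missing_fraction:.2f}%)")
    print(f"planted phenotypes: {dict(truth.labels.value_counts().sort_index())}")
    print(f"network: {net.n_reactions} reactions / {net.n_metabolites} metabolites, "
          f"{len(net.transport_ids)} transports")


if __name__ == "__main__":
    main()
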