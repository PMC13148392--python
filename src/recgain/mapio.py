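"""Text serialisation: PLINK-MAP-dialect genetic maps and effect tables.

The map dialect has four whitespace-separated columns — chromosome, locus
id, cM position, bp position (written as 0) — one locus per line, grouped by
chromosome in map order.  The dialect carries no separate chromosome-length
field, so on reading the chromosome length is taken as the last locus
position; this is exact for maps whose final locus is pinned to the
chromosome end (as the default map generator guarantees).
"""
from __future__ import annotations

import numpy as np

from .genome import GeneticMap
from .gs import GsModel
from .traits import SnpChip, TraitArchitecture

__all__ = [
    "write_map",
    "read_map",
    "write_architecture",
    "read_architecture",
    "write_chip",
    "read_chip",
    "write_gs_model",
    "read_gs_model",
]


def write_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for c in range(gmap.n_chrom):
            sl = gmap.chrom_slice(c)
            name = gmap.chrom_names[c]
            for lid, pos in zip(gmap.locus_ids[sl], gmap.positions[sl]):
                fh.write(f"{name}\t{lid}\t{float(pos)!r}\t0\n")


def read_map(path, factor: float = 1.0) -> GeneticMap:
    chroms: list[str] = []
    ids: list[str] = []
    pos: list[float] = []
    starts = [0]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, lid, cm, _bp = line.split()
            if not chroms or c != chroms[-1]:
                chroms.append(c)
                if len(chroms) > 1:
                    starts.append(len(pos))
            ids.append(lid)
            pos.append(float(cm))
    starts.append(len(pos))
    positions = np.asarray(pos)
    lengths = np.array([positions[starts[c + 1] - 1] for c in range(len(chroms))])
    return GeneticMap(
        chrom_names=tuple(chroms),
        chrom_starts=np.asarray(starts, dtype=np.int64),
        positions=positions,
        lengths=lengths,
        locus_ids=np.array(ids, dtype=object),
        factor=factor,
    )


def write_architecture(arch: TraitArchitecture, gmap: GeneticMap, path) -> None:
    """QTL table (chromosome, locus id, effect) with a metadata header."""
    chrom_of = np.searchsorted(gmap.chrom_starts[1:], arch.qtl_idx, side="right")
    with open(path, "w") as fh:
        fh.write(f"# sigma_e2={float(arch.sigma_e2)!r}\th2_target={float(arch.h2_target)!r}\n")
        for i, (q, a) in enumerate(zip(arch.qtl_idx, arch.effects)):
            fh.write(f"{gmap.chrom_names[chrom_of[i]]}\t{gmap.locus_ids[q]}\t{float(a)!r}\t{q}\n")


def read_architecture(path) -> TraitArchitecture:
    idx, eff = [], []
    sigma_e2 = h2 = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                fields = dict(kv.split("=") for kv in line[1:].split())
                sigma_e2 = float(fields["sigma_e2"])
                h2 = float(fields["h2_target"])
                continue
            _c, _lid, a, q = line.split()
            idx.append(int(q))
            eff.append(float(a))
    return TraitArchitecture(np.asarray(idx), np.asarray(eff), sigma_e2, h2)


def write_chip(chip: SnpChip, gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for i in chip.marker_idx:
            fh.write(f"{gmap.locus_ids[i]}\t{i}\n")


def read_chip(path) -> SnpChip:
    idx = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                idx.append(int(line.split()[1]))
    return SnpChip(np.asarray(idx))


def write_gs_model(model: GsModel, path, locus_ids=None) -> None:
    """Effect table with a metadata block (lambda, training generations...)."""
    with open(path, "w") as fh:
        fh.write(f"# intercept={float(model.intercept)!r}\n")
        fh.write(f"# lambda={float(model.lambda_)!r}\tsigma_u2={float(model.sigma_u2)!r}"
                 f"\tsigma_e2={float(model.sigma_e2)!r}\n")
        fh.write(f"# map_factor_at_training={float(model.map_factor_at_training)!r}\n")
        fh.write(f"# training_generations={','.join(map(str, model.training_generations))}\n")
        for j, (u, m) in enumerate(zip(model.marker_effects, model.col_means)):
            lid = locus_ids[j] if locus_ids is not None else f"m{j}"
            fh.write(f"{lid}\t{float(u)!r}\t{float(m)!r}\n")


def read_gs_model(path) -> GsModel:
    meta: dict[str, str] = {}
    eff, means = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for kv in line[1:].strip().split("\t"):
                    k, v = kv.split("=", 1)
                    meta[k.strip()] = v
                continue
            _lid, u, m = line.split()
            eff.append(float(u))
            means.append(float(m))
    gens = tuple(g for g in meta.get("training_generations", "").split(",") if g)
    return GsModel(
        intercept=float(meta["intercept"]),
        marker_effects=np.asarray(eff),
        col_means=np.asarray(means),
        lambda_=float(meta["lambda"]),
        sigma_u2=float(meta["sigma_u2"]),
        sigma_e2=float(meta["sigma_e2"]),
        training_generations=gens,
        map_factor_at_training=float(meta["map_factor_at_training"]),
    )
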