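"""HDF5 container for stimulus-response datasets and interpretation artifacts.

Layout (version 1)::

    /cochleagrams/<clip_id>          values (F, T), freqs (F,); attr dt
    /responses/<neuron_id>/<clip_id> trials (M, T), psth (T,); attr modality
    /interpret/<model_id>/<neuron_id>  gradmap / dream datasets (optional)
    root attrs: population_mode, version, clip_order, split_labels (optional)

An NPZ export mirror is provided for small fixtures.  Converters for the
public CRCNS aa-1 / ac-1, Zenodo 7796574 and OSF ayw2p archives are
documented stubs only: they describe the expected source layout but are not
exercised by the test suite (the archives require large external downloads).
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .data import Clip, Cochleagram, EncodingDataset, NeuronRecord

FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when a container is missing required groups or fields."""


def write_dataset(dataset: EncodingDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["population_mode"] = dataset.population_mode
        clip_ids = [c.cochleagram.clip_id for c in dataset.clips]
        f.attrs["clip_order"] = json.dumps(clip_ids)
        f.attrs["neurons"] = json.dumps(dataset.neurons)
        if dataset.split_labels is not None:
            f.attrs["split_labels"] = json.dumps(dataset.split_labels)
        coch = f.create_group("cochleagrams")
        resp = f.create_group("responses")
        for clip in dataset.clips:
            g = coch.create_group(clip.cochleagram.clip_id)
            g.create_dataset("values", data=clip.cochleagram.values)
            g.create_dataset("freqs", data=clip.cochleagram.freqs)
            g.attrs["dt"] = clip.cochleagram.dt
            for nid, rec in clip.responses.items():
                ng = resp.require_group(nid)
                cg = ng.create_group(clip.cochleagram.clip_id)
                cg.create_dataset("trials", data=rec.trials)
                cg.create_dataset("psth", data=rec.psth)
                cg.attrs["modality"] = rec.modality


def read_dataset(path) -> EncodingDataset:
    with h5py.File(path, "r") as f:
        for group in ("cochleagrams", "responses"):
            if group not in f:
                raise FormatError(f"missing required group {group!r}")
        clip_ids = json.loads(f.attrs["clip_order"])
        neurons = json.loads(f.attrs["neurons"])
        split = (json.loads(f.attrs["split_labels"])
                 if "split_labels" in f.attrs else None)
        clips = []
        for cid in clip_ids:
            g = f["cochleagrams"][cid]
            if "values" not in g or "freqs" not in g:
                raise FormatError(f"cochleagram {cid!r} missing values/freqs")
            coch = Cochleagram(values=g["values"][()], freqs=g["freqs"][()],
                               dt=float(g.attrs["dt"]), clip_id=cid)
            responses = {}
            for nid in neurons:
                if nid in f["responses"] and cid in f["responses"][nid]:
                    cg = f["responses"][nid][cid]
                    responses[nid] = NeuronRecord(
                        trials=cg["trials"][()], psth=cg["psth"][()],
                        modality=str(cg.attrs.get("modality", "spikes")))
            clips.append(Clip(cochleagram=coch, responses=responses))
        return EncodingDataset(
            clips=clips, neurons=neurons,
            population_mode=bool(f.attrs["population_mode"]),
            split_labels=split)


def save_interpretation(path, model_id: str, neuron_id: str, *,
                        gradmap=None, dream=None, meta: dict | None = None) -> None:
    """Store GradMap/Dream arrays under /interpret/<model_id>/<neuron_id>."""
    with h5py.File(path, "a") as f:
        g = f.require_group("interpret").require_group(model_id).require_group(
            neuron_id)
        if gradmap is not None:
            if "gradmap" in g:
                del g["gradmap"]
            g.create_dataset("gradmap", data=np.asarray(gradmap))
        if dream is not None:
            if "dream" in g:
                del g["dream"]
            g.create_dataset("dream", data=np.asarray(dream))
        g.attrs["meta"] = json.dumps(meta or {})


def write_dataset_npz(dataset: EncodingDataset, path) -> None:
    """Flat NPZ mirror of the HDF5 layout, for tiny text-free fixtures."""
    payload = {
        "__meta__": np.frombuffer(json.dumps({
            "population_mode": dataset.population_mode,
            "neurons": dataset.neurons,
            "clip_order": [c.cochleagram.clip_id for c in dataset.clips],
            "split_labels": dataset.split_labels,
        }).encode(), dtype=np.uint8)}
    for clip in dataset.clips:
        cid = clip.cochleagram.clip_id
        payload[f"coch:{cid}:values"] = clip.cochleagram.values
        payload[f"coch:{cid}:freqs"] = clip.cochleagram.freqs
        payload[f"coch:{cid}:dt"] = np.array(clip.cochleagram.dt)
        for nid, rec in clip.responses.items():
            payload[f"resp:{nid}:{cid}:trials"] = rec.trials
            payload[f"resp:{nid}:{cid}:psth"] = rec.psth
    np.savez(path, **payload)


def read_dataset_npz(path) -> EncodingDataset:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        clips = []
        for cid in meta["clip_order"]:
            coch = Cochleagram(values=f[f"coch:{cid}:values"],
                               freqs=f[f"coch:{cid}:freqs"],
                               dt=float(f[f"coch:{cid}:dt"]), clip_id=cid)
            responses = {}
            for nid in meta["neurons"]:
                key = f"resp:{nid}:{cid}:trials"
                if key in f:
                    responses[nid] = NeuronRecord(
                        trials=f[key], psth=f[f"resp:{nid}:{cid}:psth"])
            clips.append(Clip(cochleagram=coch, responses=responses))
        return EncodingDataset(clips=clips, neurons=meta["neurons"],
                               population_mode=meta["population_mode"],
                               split_labels=meta["split_labels"])


# ------------------------------------------------------------- converters

def convert_crcns_aa1(source_dir, out_path):  # pragma: no cover - stub
    """Convert a CRCNS "aa-1" download (zebra finch MLd / Field L).

    Expected source layout: per-unit directories with stimulus spectrogram
    matrices (32 mel bands, 1 ms bins) and spike-time files per trial; spike
    trains should be binned at the spectrogram resolution and PSTHs smoothed
    with a 21 ms Hanning window.  Not implemented here: the archive requires
    a CRCNS account and a multi-GB download.
    """
    raise NotImplementedError("documented stub; see the module docstring")


def convert_crcns_ac1(source_dir, out_path):  # pragma: no cover - stub
    """Convert the whole-cell subset of CRCNS "ac-1" (rat A1/MGB).

    Membrane-potential traces at 5 ms bins with 54 log-spaced bands;
    responses should be detrended with ``data.detrend_medgauss`` before
    writing.  Not implemented (external download).
    """
    raise NotImplementedError("documented stub; see the module docstring")


def convert_zenodo_7796574(source_dir, out_path):  # pragma: no cover - stub
    """Convert the Zenodo record 7796574 archive (NAT4 A1/PEG)."""
    raise NotImplementedError("documented stub; see the module docstring")


def convert_osf_ayw2p(source_dir, out_path):  # pragma: no cover - stub
    """Convert the OSF "ayw2p" archive (NS1 and Wehr datasets)."""
    raise NotImplementedError("documented stub; see the module docstring")
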