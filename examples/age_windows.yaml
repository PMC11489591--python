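# Example glacial/interglacial age windows (ka BP) for interval_stats.
# Window boundaries follow common marine-isotope-stage usage; adjust per core.
late_holocene: [0, 4]
holocene: [0, 12]
lgm: [19, 26]
mis5e: [116, 128]
mis6: [135, 155]
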