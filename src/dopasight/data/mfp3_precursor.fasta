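>MFP3_precursor Q9GUX8 mussel foot protein 3 precursor; signal 1-24, mature 25-70
MNNISVAVLVALVLIGSFAVQSDAADYYGPKYGPPRRYGGGNYNRYGRRYGGYKGWNNGW
KRGRWGRKYY
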