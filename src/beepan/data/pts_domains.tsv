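# Domain accession -> PTS EII class map (editable).
# Accessions cover the common EIIA/EIIB/EIIC/EIID domain families of the
# mannose/fructose/sorbose and related PTS transporters.
PF00358	PTS_EIIA
PF03610	PTS_EIIA
PF00359	PTS_EIIA
PF00367	PTS_EIIB
PF03830	PTS_EIIB
PF02302	PTS_EIIB
PF02378	PTS_EIIC
PF03609	PTS_EIIC
PF02255	PTS_EIIC
PF03613	PTS_EIID
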