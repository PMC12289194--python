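animal_id,t,lat,lon,dop
A01,2019-06-02 12:00:00,50.00,14.80,2.0
A01,2019-06-02 12:30:00,50.01,14.80,2.0
A01,2019-06-02 13:00:00,50.01,14.81,2.0
A01,2019-06-02 13:30:00,50.00,14.81,2.0
A01,2019-06-02 14:00:00,50.00,14.80,2.0
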