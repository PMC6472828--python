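species,min_len,lower_break,upper_break,max_len
American Plaice,7.0,22.6,38.3,54.0
Atlantic Cod,13.0,45.9,80.0,113.0
Capelin,11.0,13.6,16.2,18.8
Greenland Halibut,10.0,27.4,45.0,62.5
Lanternfish,12.9,14.5,15.6,17.4
Redfish,4.0,18.6,33.2,48.0
Thorny Skate,10.2,33.9,58.3,80.0
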