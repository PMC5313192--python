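location,latitude,tl_inf,fl_inf,pcl_inf,k,g130,n,method,l0
GBR Australia,14.7-19.3 S,229.2,188.61,173.33,0.05,5.08,89,age-length VBGF,57.5
Papua New Guinea,2.0-12.0 S,163.0,,,0.15,5.33,133,age-length VBGF,72.0
NW Hawaiian Islands,23.1-28.2 N,173.3,,134.0,0.29,14.68,62,age-length VBGF,60.0
Palmyra Atoll,5.8-5.9 N,163.3,,,0.054,1.75,118,tag-recapture increments,60.0
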