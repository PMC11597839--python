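# Ertl fragment contributions to topological polar surface area (version 1.0,
# including the S/P extension). One row per polar-atom environment. An atom's
# environment signature is (element, aromatic flag, formal charge, attached H,
# single/double/triple/aromatic bond counts, 3-ring membership); the nitro
# group is normalised to its neutral pentavalent form before assignment.
# Contributions in Angstrom^2.
element,aromatic,charge,n_h,n_single,n_double,n_triple,n_aromatic,ring3,contribution,pattern
N,0,0,0,3,0,0,0,0,3.24,N(-*)(-*)-*
N,0,0,0,1,1,0,0,0,12.36,N(-*)=*
N,0,0,0,0,0,1,0,0,23.79,N#*
N,0,0,0,1,2,0,0,0,11.68,N(-*)(=*)=* nitro
N,0,0,0,0,1,1,0,0,13.60,N(=*)#*
N,0,0,0,3,0,0,0,1,3.01,N 3-ring
N,0,0,1,2,0,0,0,0,12.03,NH(-*)-*
N,0,0,1,2,0,0,0,1,21.94,NH 3-ring
N,0,0,1,0,1,0,0,0,23.85,NH=*
N,0,0,2,1,0,0,0,0,26.02,NH2-*
N,0,1,0,4,0,0,0,0,0.00,N+(-*)(-*)(-*)-*
N,0,1,0,2,1,0,0,0,3.01,N+(-*)(-*)=*
N,0,1,0,1,0,1,0,0,4.36,N+(-*)#*
N,0,1,1,3,0,0,0,0,4.44,NH+(-*)(-*)-*
N,0,1,1,1,1,0,0,0,13.97,NH+(-*)=*
N,0,1,2,2,0,0,0,0,16.61,NH2+(-*)-*
N,0,1,2,0,1,0,0,0,25.59,NH2+=*
N,0,1,3,1,0,0,0,0,27.64,NH3+-*
N,1,0,0,0,0,0,2,0,12.89,n(:*):*
N,1,0,0,0,0,0,3,0,4.41,n(:*)(:*):*
N,1,0,0,1,0,0,2,0,4.93,n(-*)(:*):*
N,1,0,0,0,1,0,2,0,8.39,n(=*)(:*):*
N,1,0,1,0,0,0,2,0,15.79,nH(:*):*
N,1,1,0,0,0,0,3,0,4.10,n+(:*)(:*):*
N,1,1,0,1,0,0,2,0,3.88,n+(-*)(:*):*
N,1,1,1,0,0,0,2,0,14.14,nH+(:*):*
O,0,0,0,2,0,0,0,0,9.23,O(-*)-*
O,0,0,0,2,0,0,0,1,12.53,O 3-ring
O,0,0,0,0,1,0,0,0,17.07,O=*
O,0,0,1,1,0,0,0,0,20.23,OH-*
O,0,-1,0,1,0,0,0,0,23.06,O--*
O,1,0,0,0,0,0,2,0,13.14,o(:*):*
S,0,0,0,2,0,0,0,0,25.30,S(-*)-*
S,0,0,0,0,1,0,0,0,32.09,S=*
S,0,0,0,2,1,0,0,0,19.21,S(-*)(-*)=*
S,0,0,0,2,2,0,0,0,8.38,S(-*)(-*)(=*)=*
S,0,0,1,1,0,0,0,0,38.80,SH-*
S,1,0,0,0,0,0,2,0,28.24,s(:*):*
S,1,0,0,0,1,0,2,0,21.70,s(=*)(:*):*
P,0,0,0,3,0,0,0,0,13.59,P(-*)(-*)-*
P,0,0,0,1,1,0,0,0,34.14,P(-*)=*
P,0,0,0,3,1,0,0,0,9.81,P(-*)(-*)(-*)=*
P,0,0,1,2,1,0,0,0,23.47,PH(-*)(-*)=*
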