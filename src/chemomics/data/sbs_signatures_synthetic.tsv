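# Stylized SYNTHETIC stand-in for SBS1/SBS2/SBS5/SBS13 trinucleotide
# signature probabilities (pyrimidine-strand 96-channel convention).
# Not COSMIC release values. Channel order: C>A,C>G,C>T,T>A,T>C,T>G x 5p x 3p (A,C,G,T).
channel	SBS1	SBS2	SBS5	SBS13
A[C>A]A	0.00347826	0.00239130	0.00879356	0.00260870
A[C>A]C	0.00347826	0.00239130	0.00896947	0.00260870
A[C>A]G	0.00347826	0.00239130	0.00859913	0.00260870
A[C>A]T	0.00347826	0.00239130	0.00785673	0.00260870
C[C>A]A	0.00347826	0.00239130	0.00709142	0.00260870
C[C>A]C	0.00347826	0.00239130	0.00666314	0.00260870
C[C>A]G	0.00347826	0.00239130	0.00677332	0.00260870
C[C>A]T	0.00347826	0.00239130	0.00737014	0.00260870
G[C>A]A	0.00347826	0.00239130	0.00817291	0.00260870
G[C>A]C	0.00347826	0.00239130	0.00880406	0.00260870
G[C>A]G	0.00347826	0.00239130	0.00896677	0.00260870
G[C>A]T	0.00347826	0.00239130	0.00858450	0.00260870
T[C>A]A	0.00347826	0.00239130	0.00783705	0.00260870
T[C>A]C	0.00347826	0.00239130	0.00707594	0.00260870
T[C>A]G	0.00347826	0.00239130	0.00665915	0.00260870
T[C>A]T	0.00347826	0.00239130	0.00678270	0.00260870
A[C>G]A	0.00347826	0.00239130	0.00703485	0.00260870
A[C>G]C	0.00347826	0.00239130	0.00717558	0.00260870
A[C>G]G	0.00347826	0.00239130	0.00687931	0.00260870
A[C>G]T	0.00347826	0.00239130	0.00628538	0.00260870
C[C>G]A	0.00347826	0.00239130	0.00567313	0.00260870
C[C>G]C	0.00347826	0.00239130	0.00533051	0.00260870
C[C>G]G	0.00347826	0.00239130	0.00541866	0.00260870
C[C>G]T	0.00347826	0.00239130	0.00589611	0.00260870
G[C>G]A	0.00347826	0.00239130	0.00653833	0.00260870
G[C>G]C	0.00347826	0.00239130	0.00704325	0.00260870
G[C>G]G	0.00347826	0.00239130	0.00717342	0.00260870
G[C>G]T	0.00347826	0.00239130	0.00686760	0.00260870
T[C>G]A	0.00347826	0.00239130	0.00626964	0.22000000
T[C>G]C	0.00347826	0.00239130	0.00566075	0.08000000
T[C>G]G	0.00347826	0.00239130	0.00532732	0.04000000
T[C>G]T	0.00347826	0.00239130	0.00542616	0.42000000
A[C>T]A	0.00347826	0.00239130	0.01758713	0.00260870
A[C>T]C	0.00347826	0.00239130	0.01793894	0.00260870
A[C>T]G	0.17000000	0.00239130	0.01719827	0.00260870
A[C>T]T	0.00347826	0.00239130	0.01571346	0.00260870
C[C>T]A	0.00347826	0.00239130	0.01418284	0.00260870
C[C>T]C	0.00347826	0.00239130	0.01332628	0.00260870
C[C>T]G	0.17000000	0.00239130	0.01354665	0.00260870
C[C>T]T	0.00347826	0.00239130	0.01474029	0.00260870
G[C>T]A	0.00347826	0.00239130	0.01634581	0.00260870
G[C>T]C	0.00347826	0.00239130	0.01760813	0.00260870
G[C>T]G	0.17000000	0.00239130	0.01793354	0.00260870
G[C>T]T	0.00347826	0.00239130	0.01716900	0.00260870
T[C>T]A	0.00347826	0.25000000	0.01567409	0.00260870
T[C>T]C	0.00347826	0.08000000	0.01415189	0.00260870
T[C>T]G	0.17000000	0.05000000	0.01331830	0.00260870
T[C>T]T	0.00347826	0.40000000	0.01356539	0.00260870
A[T>A]A	0.00347826	0.00239130	0.00791421	0.00260870
A[T>A]C	0.00347826	0.00239130	0.00807252	0.00260870
A[T>A]G	0.00347826	0.00239130	0.00773922	0.00260870
A[T>A]T	0.00347826	0.00239130	0.00707106	0.00260870
C[T>A]A	0.00347826	0.00239130	0.00638228	0.00260870
C[T>A]C	0.00347826	0.00239130	0.00599683	0.00260870
C[T>A]G	0.00347826	0.00239130	0.00609599	0.00260870
C[T>A]T	0.00347826	0.00239130	0.00663313	0.00260870
G[T>A]A	0.00347826	0.00239130	0.00735562	0.00260870
G[T>A]C	0.00347826	0.00239130	0.00792366	0.00260870
G[T>A]G	0.00347826	0.00239130	0.00807009	0.00260870
G[T>A]T	0.00347826	0.00239130	0.00772605	0.00260870
T[T>A]A	0.00347826	0.00239130	0.00705334	0.00260870
T[T>A]C	0.00347826	0.00239130	0.00636835	0.00260870
T[T>A]G	0.00347826	0.00239130	0.00599324	0.00260870
T[T>A]T	0.00347826	0.00239130	0.00610443	0.00260870
A[T>C]A	0.00347826	0.00239130	0.02198391	0.00260870
A[T>C]C	0.00347826	0.00239130	0.02242368	0.00260870
A[T>C]G	0.00347826	0.00239130	0.02149784	0.00260870
A[T>C]T	0.00347826	0.00239130	0.01964182	0.00260870
C[T>C]A	0.00347826	0.00239130	0.01772855	0.00260870
C[T>C]C	0.00347826	0.00239130	0.01665785	0.00260870
C[T>C]G	0.00347826	0.00239130	0.01693331	0.00260870
C[T>C]T	0.00347826	0.00239130	0.01842536	0.00260870
G[T>C]A	0.00347826	0.00239130	0.02043227	0.00260870
G[T>C]C	0.00347826	0.00239130	0.02201016	0.00260870
G[T>C]G	0.00347826	0.00239130	0.02241692	0.00260870
G[T>C]T	0.00347826	0.00239130	0.02146125	0.00260870
T[T>C]A	0.00347826	0.00239130	0.01959261	0.00260870
T[T>C]C	0.00347826	0.00239130	0.01768986	0.00260870
T[T>C]G	0.00347826	0.00239130	0.01664788	0.00260870
T[T>C]T	0.00347826	0.00239130	0.01695674	0.00260870
A[T>G]A	0.00347826	0.00239130	0.00703485	0.00260870
A[T>G]C	0.00347826	0.00239130	0.00717558	0.00260870
A[T>G]G	0.00347826	0.00239130	0.00687931	0.00260870
A[T>G]T	0.00347826	0.00239130	0.00628538	0.00260870
C[T>G]A	0.00347826	0.00239130	0.00567313	0.00260870
C[T>G]C	0.00347826	0.00239130	0.00533051	0.00260870
C[T>G]G	0.00347826	0.00239130	0.00541866	0.00260870
C[T>G]T	0.00347826	0.00239130	0.00589611	0.00260870
G[T>G]A	0.00347826	0.00239130	0.00653833	0.00260870
G[T>G]C	0.00347826	0.00239130	0.00704325	0.00260870
G[T>G]G	0.00347826	0.00239130	0.00717342	0.00260870
G[T>G]T	0.00347826	0.00239130	0.00686760	0.00260870
T[T>G]A	0.00347826	0.00239130	0.00626964	0.00260870
T[T>G]C	0.00347826	0.00239130	0.00566075	0.00260870
T[T>G]G	0.00347826	0.00239130	0.00532732	0.00260870
T[T>G]T	0.00347826	0.00239130	0.00542616	0.00260870
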