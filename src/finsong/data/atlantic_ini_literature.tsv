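Region	Recording months	Recording years	INI pattern	Source
Mid-Atlantic Ridge (MARI)	Jan, Dec	1999-2000	~20 s	Hatch & Clark 2004, Fig. 4
Western Tropical North Atlantic (WTNA)	Jan, Feb, Mar, Dec	1993-1994	~12-14 s	Hatch & Clark 2004, Fig. 4
Central Western North Atlantic (CWNA)	Jan, Feb	1993-1994	~13-14 s	Hatch & Clark 2004, Fig. 4
Bermuda	All months	1958-1960; 1967-1968; 1978-1979	~18 s (Feb-Apr); ~14 s (Nov-Jan)	Watkins et al. 1987, Fig. 17
NYB/GoM	All months	2008-2009	~15 s (Mar-May); ~10 s (Sep-Jan)	Morano et al. 2012, Fig. 3
Northwestern Atlantic (NWNA)	Jan, Feb, Mar, Apr, Nov, Dec	1994-1995; 2002-2003	~8-10 s; ~14-15 s	Hatch & Clark 2004, Fig. 4
GoM	Jan, Feb, Mar, Aug, Sep, Oct, Nov, Dec	2006; 2007	~15 s (Jan-Mar); ~9 s (Sep-Jan)	Delarue et al. 2009, Tab. 2 & Fig. 6
GSL	Sep, Oct, Nov, Dec	2005	~11-12 s (Sep-Dec)	Delarue et al. 2009, Tab. 2
Davis Strait	All months	2006-2008	~13.5 s (Oct-Nov)	Simon et al. 2010
North Eastern North Atlantic (NENA)	All months	1993-1995; 1997-2002	~10-12 s; ~18-19 s	Hatch & Clark 2004, Fig. 4
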